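# Cis-regulatory element catalog: PlantCARE-style exact/IUPAC consensus
# strings for the element names profiled in dehydrin promoters. Editable data,
# not code: swap in alternative consensi without touching the scanner.
# name	category	consensus (comma-separated variants)
G-box	LIGHT	CACGTG,GACGTG
Box 4	LIGHT	ATTAAT
ABRE	HORMONE	ACGTG
CGTCA-motif	HORMONE	CGTCA
TGACG-motif	HORMONE	TGACG
AuxRR-core	HORMONE	GGTCCAT
TGA-element	HORMONE	AACGAC
SARE	HORMONE	TTCGACCATCTT
P-box	HORMONE	CCTTTTG
TATC-box	HORMONE	TATCCCA
GARE-motif	HORMONE	TCTGTTG
MYC	STRESS	CATTTG,CAATTG,CATGTG
ARE	STRESS	AAACCA
as-1	STRESS	TGACGTCA
MYB	STRESS	CAACCA,TAACCA
MBS	STRESS	CAACTG
LTR	STRESS	CCGAAA
DRE core	STRESS	GCCGAC
W box	STRESS	TTGACC
WRE3	STRESS	CCACCT
TC-rich repeats	STRESS	ATTTTCTTCA
WUN-motif	STRESS	AAATTTCCT
CAT-box	DEVELOPMENT	GCCACT
RY-element	DEVELOPMENT	CATGCATG
GCN4_motif	DEVELOPMENT	TGAGTCA
circadian	DEVELOPMENT	CAANNNNATC
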