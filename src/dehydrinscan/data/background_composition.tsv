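# Phi-segment (linker) background amino-acid composition for the synthetic
# generator: Gly/Thr-rich, charged/polar-elevated, aromatic/aliphatic-poor,
# so generated dehydrins are hydrophilic and disordered by construction.
# residue	prob
G	0.140
T	0.100
E	0.100
D	0.090
K	0.110
H	0.050
S	0.090
N	0.060
Q	0.050
A	0.060
P	0.060
R	0.050
M	0.010
Y	0.010
V	0.004
L	0.004
I	0.004
F	0.004
W	0.002
C	0.002
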