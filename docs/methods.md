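# Methods

`dehydrinscan` analyses dehydrins — group-2 LEA proteins (Pfam PF00257) —
the way comparative studies of woody-plant dehydrins are done: locate the
conserved K/Y/S/F segments, type each protein's architecture, compute the
biochemical properties that characterise intrinsically disordered,
hydrophilic proteins, compare taxon groups, and profile cis-regulatory
elements in promoters. This note documents the models, the parameter
choices and their rationale, and what the synthetic-data generator does and
does not emulate.

## Segment model

Each conserved segment class is described twice: by a degenerate consensus
pattern (per-position allowed residue sets, with a designated *core* that
must match exactly) and by a position-specific probability matrix (PSPM)
used for scoring.

| class | width | pattern (0-based) | core |
|---|---|---|---|
| K | 15 | X K X G X X {DE} K {IV} K {DE} K X P G | 3-G, 7-K, 8-{I,V}, 9-K, 13-P, 14-G |
| Y | 7 | D {DE} {YHF} G N P X | 0-D, 3-G, 4-N, 5-P |
| S | 13–17 | L H R {ST} G + S×(4–8) + {SDE} {DE} {DE} {DE} | the Ser tract |
| F | 12 | E X X D R G X F D F X {GK} | 7-F, 9-F |

The K core is the obligatory Gly/Pro scaffold plus the Lys-Ile-Lys tripeptide
whose hydrophobic centre tolerates the conservative Ile→Val substitution
(observed at ~12%). The Y core is the DxxGNP frame; the F core is the
phenylalanine dyad that names the segment.

A window is a match when the core matches exactly, at most
`mismatch_budget` (default 2) non-core positions fall outside their allowed
sets, and the PSPM log-odds score against a uniform 1/20 background reaches
`score_threshold` (default 0 bits). The defaults accept the textbook
consensus of every class while rejecting uniform-random windows at a
per-window false-positive rate below 10⁻³ (measured by simulation in the
test suite and the acceptance script); both are exposed on the CLI.

**S-tract length.** Published descriptions of the S segment disagree on the
tract length (4–6, "usually 4–8", and a modal seven consecutive serines).
The scanner accepts maximal runs of 4–8 and records the observed run
length; runs of 9+ are not S segments under this definition. The residue
position after the tract admits Ser/Asp/Glu in scanning, but the synthetic
generator draws it from {D, E} only, so a planted tract's right boundary is
never ambiguous and exact-coordinate recovery is well defined.

**PSPM construction.** Each column starts from the frequencies reported for
the class's sequence LOGO (e.g. K-segment Lys 81–90% at its Lys positions,
Y-segment Asp 96%/Tyr 62%, S-anchor Leu 87%/His 81%/Arg 86%/Ser 80%,
F-segment Phe 98%/81%); the remaining mass is spread uniformly over the
residues the degenerate pattern allows at that position, and a pseudocount
of 10⁻⁴ over all 20 residues removes zeros before renormalisation. For the
F segment, whose published LOGO carries two to three extra N-terminal
columns relative to the 12-wide bracket pattern, the quoted frequencies are
mapped onto the bracket by their consistent offset, and the terminal Lys
(97%) goes to the bracket's final {G,K} position. The Leu-Phe-Asp-Phe-Leu
hydrophobic core weights the two X positions flanking the dyad (P(L)=0.30)
in scoring only — they are not anchored. The S matrix uses a 16-column
reference layout (anchor 5 + modal 7-Ser tract + tail 4); variable-width
matches map tract residues onto the tract columns.

**Overlap resolution** is greedy by descending score, ties to the smaller
start, and forbids overlap across classes as well as within one: a residue
belongs to one segment.

## Architecture typing

The ordered letters of the resolved segments (ascending start) are matched
against the grammar of the seven canonical names, first match wins:

    K+ · SK+ · K+S · Y+K+ · Y+SK+ · FSK+ · F+K+

Everything else — Y after K, S interior to the K block, F together with Y,
multiple S blocks — is *atypical*, mirroring how unusual architectures are
set aside rather than forced into a named type. FSKn is read strictly
(exactly one F, one S): a hypothetical F₂SK₃ falls to atypical, since the
name subscripts neither F nor S; F+K+ (no S) admits multiple F copies, as
observed in nature. A sequence without a K segment is not a dehydrin and is
an error at this stage (the pipeline routes such records to a rejects
file).

Rare motifs are literal: a K segment is His-His-flanked only when both the
two residues before and after it are `HH`; the poly-lysine motif is the
exact 8-mer `KKKKKEKK` (a relaxed `K{4,}EK{1,3}` count is reported as a
diagnostic only); His-His-richness counts non-overlapping `HH` dimers
(threshold ≥ 4, so `HHH` counts once); the metal-binding HH-X₃-HH motif is
`HHSGDHH`.

## Biochemical properties

All averages run over non-X residues; X is retained in sequences but has no
physical constants. Constants ship as editable plain-text tables.

- **Molecular weight**: sum of average residue masses (ExPASy convention)
  plus one water (18.0153 Da).
- **pI**: Henderson–Hasselbalch net charge with the Bjellqvist pKa set
  (N-term 7.5, C-term 3.55; K 10.0, R 12.0, H 5.98, D 4.05, E 4.45, C 9.0,
  Y 10.0), solved by bisection on [0, 14] to |charge| < 10⁻⁴. The charge
  curve is strictly decreasing, so the root is unique. Terminal pKa are
  sequence-independent defaults; ProtParam's residue-specific terminal
  adjustments are deliberately omitted (the table is swappable per call,
  e.g. for an EMBOSS set).
- **GRAVY**: mean Kyte–Doolittle hydropathy; negative ⇒ hydrophilic.
- **Fold index**: FI = 2.785·⟨H⟩ − |⟨R⟩| − 1.151 with ⟨H⟩ the mean of
  (KD + 4.5)/9 and ⟨R⟩ the mean net charge (K,R = +1; D,E = −1; His
  neutral, the standard convention — noted because dehydrins are
  His-variable). Negative ⇒ predicted intrinsically disordered. The
  headline value is the whole-sequence index, matching how one number per
  protein is plotted; a 51-residue windowed profile is available.

## Group statistics

Per-group five-number summaries use linear-interpolation quartiles. The
pairwise comparison is Games–Howell: Welch standard error
√(s²ᵢ/nᵢ + s²ⱼ/nⱼ), Welch–Satterthwaite df, q = |mᵢ−mⱼ|/√(SE²/2), p from
the studentized range distribution with k groups — familywise control
without equal-variance or equal-n assumptions. (The procedure is sometimes
loosely called non-parametric; it is the Welch/studentized-range procedure
and assumes normality but not homoscedasticity.) The studentized-range CDF
is scipy's exact double-integral quadrature; the test suite checks it
against an independent Gauss–Legendre quadrature oracle to 10⁻⁴ and checks
the procedure's type-I error by simulation (5,000 null datasets with
variances 1/4/9: familywise rejection ≈ 0.045 at α = 0.05). No additional
multiple-testing correction is applied on top. Quantities whose location
is reported per group are summarised as medians.

## Promoter cis-element analysis

Elements are named IUPAC consensus strings (PlantCARE-style exact matching;
no position-weight scoring), scanned on both strands; `N` in a promoter
matches nothing. Hit coordinates are 0-based half-open on the forward
sequence with a strand flag; `matched_seq` reads in the strand's
orientation. The headline quantity is per-element *presence*: the
percentage of promoters containing the element at least once. CGTCA-motif
and TGACG-motif — the two strand reads of the same MeJA-responsive element
— are catalogued under their own names with a derived union flag.

The shipped catalog compiles PlantCARE-convention consensus strings for the
element names profiled in dehydrin promoters. PlantCARE's own matrices are
not public data here, so the catalog is data, not code: bar-height fidelity
against any external report depends on catalog fidelity and the catalog
file can be swapped wholesale.

## Synthetic data: what it emulates, what it does not

The generator emulates the *structure* of a woody-plant dehydrin dataset:

- **Proteins**: segments sampled from the class PSPMs restricted to the
  degenerate pattern, embedded in Φ-background linkers of 10–60 residues
  (5–30 at the termini). The background composition (shipped as data) is
  Gly 14%, Thr 10%, elevated charged/polar residues, suppressed
  aromatics/aliphatics — chosen once so that generated dehydrins are
  hydrophilic and disordered by construction (GRAVY ≈ −2, FI ≈ −0.4 for
  pure background), mirroring the universal negativity observed in real
  dehydrins. Mutations, when requested, touch only non-core segment
  positions, so plants stay recoverable within the default mismatch budget.
- **Cohorts**: per-group architecture-type weights default to the observed
  woody-plant distribution (gymnosperm trees: FSKn 56.3%, FnKn 21%;
  angiosperm trees/shrubs: FSKn 39.5%, YnSKn 20%; vines: YnSKn 69.4%,
  FSKn 22.2%; Y-types absent from gymnosperms, Kn/YnKn/FnKn absent from
  vines; remainders spread over the remaining legal types). K copy numbers
  follow a decaying distribution over 1–9; Y mostly 1–2 copies; F 1–2.
  Default cohort sizes are the study's 32/185/36.
- **Promoters**: uniform-ACGT background with elements planted verbatim or
  reverse-complemented at chosen coordinates. Because short consensi occur
  by chance in 2 kb of random DNA, the generator can scrub the background
  against a catalog (resampling background positions until the only hits
  are the planted ones), which makes exact-incidence experiments possible.
  Elements nested inside other planted elements (e.g. reverse-complement
  pairs) cannot be scrubbed and raise an error rather than silently
  corrupting the truth.

Not emulated: phylogenetic relatedness among sequences (every record is an
independent draw), fragmentary or duplicated records, real Φ-segment
length/composition heterogeneity across clades, and real promoter base
composition or element clustering. Passing recovery tests therefore
demonstrates correctness of the scanning/typing machinery under the stated
segment model, not performance on diverged natural sequences whose segments
drift outside the consensus.

## Numerical choices and degenerate inputs

- Quartiles: linear interpolation; pI bisection tolerance 10⁻⁴ charge
  units (≈ 10⁻⁴ pH resolution); PSPM pseudocount 10⁻⁴.
- Ties in overlap resolution break to the smaller start coordinate;
  resolution order is deterministic, so reruns are byte-identical.
- Empty effective sequences (all-X), unknown residues, empty groups,
  zero-variance groups, formulas without K, overlapping planting plans and
  non-IUPAC catalog letters are all hard errors, not warnings.
- Exact-sequence deduplication is provided; fragment filtering is left to
  the user (no robust sequence-only criterion exists for "fragment").

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated data:
1,000 dehydrins per recovery experiment, the 253-sequence study-sized
cohort for the biochemical universals, 1,000-per-group cohorts for
type-distribution checks, 5,000 simulated datasets for the Games–Howell
null, and 34 × 2 kb promoters for the cis-element experiments. These sizes
give binomial standard errors comfortably below the asserted margins while
keeping a full run in a few minutes on one CPU.

## Known limitations

- The scanner is a consensus/PSPM matcher, not an EM motif discoverer; it
  will not find segment variants outside the degenerate patterns.
- Catalog fidelity bounds promoter-profile fidelity; the shipped consensi
  are conventional, not a reproduction of any proprietary matrix set.
- The pI model ignores residue-specific terminal pKa adjustments and
  charge-state effects beyond Henderson–Hasselbalch.
- Games–Howell p-values are asymptotic in the Welch sense; very small
  groups (n < 5) give coarse df and should be interpreted cautiously.
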