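# dehydrinscan

Dehydrins are group-2 late embryogenesis abundant (LEA) proteins — Pfam
PF00257 — that plants accumulate under drought, cold and salinity. They are
hydrophilic, intrinsically disordered, and built from a small vocabulary of
conserved segments: the obligatory lysine-rich **K segment**
(EKKGIMDKIKEKLPG consensus), the N-terminal **Y segment** (DEYGNP core),
the phosphorylatable serine-tract **S segment** and the phenylalanine-dyad
**F segment**, separated by disordered Φ linkers. The ordered combination
of segments defines a dehydrin's *architectural type* — Kₙ, KₙS, SKₙ,
YₙKₙ, YₙSKₙ, FSKₙ, FₙKₙ — which differs systematically between taxa
(gymnosperm trees are FSKₙ/FₙKₙ-dominated; angiosperm vines are mostly
YₙSKₙ).

`dehydrinscan` is a Python package for comparative dehydrin analysis:

- **segment scanning** with degenerate consensus patterns plus
  position-specific probability matrix (PSPM) log-odds scoring,
- **architecture typing** against the seven-type grammar, with a census of
  rare motifs (His-His-flanked K segments, the KKKKKEKK poly-K motif, the
  HHSGDHH metal-binding motif),
- **biochemical profiles**: molecular weight, isoelectric point
  (Bjellqvist pKa, bisection), GRAVY, fold index
  (2.785·⟨H⟩ − |⟨R⟩| − 1.151), Lys% and His%,
- **group statistics**: five-number summaries and Games–Howell pairwise
  comparisons (Welch df + studentized range),
- **promoter analysis**: IUPAC scanning of cis-regulatory elements (ABRE,
  G-box, MYB/MYC, LTR, DRE, …) on both strands and per-element presence
  frequencies,
- a **synthetic-data generator** that plants segments and elements at
  known coordinates, so the whole pipeline is testable without downloads.

See `docs/methods.md` for the models, parameter defaults and their
rationale.

## Worked example

Generate a small cohort with ground truth, then run the protein pipeline:

```bash
dehydrinscan simulate --n-gymnosperm 3 --n-tree-shrub 3 --n-vine 2 \
    --seed 7 --fasta-out cohort.fa --truth-out truth.tsv --groups-out groups.tsv
dehydrinscan run-proteins cohort.fa --group-table groups.tsv --out-dir out
```

`out/architecture.tsv` then contains one row per sequence (coordinates are
0-based, half-open everywhere):

```
accession  group                  formula  arch_type  nK  nY  nS  nF  ...
SYN00001   gymnosperm_tree        FK5      FnKn        5   0   0   1
SYN00002   gymnosperm_tree        KS       KnS         1   0   1   0
SYN00007   angiosperm_vine        YSK3     YnSKn       3   1   1   0
```

i.e. the first gymnosperm record carries one F segment followed by five K
segments in N→C order (type FₙKₙ), and the first vine record Y, then S,
then three K (YₙSKₙ) — the architecture recovered from the scan matches
what the generator planted. `out/segments.tsv` lists every located segment with coordinates
and PSPM score; `out/biochem.tsv` the per-sequence properties (all GRAVY
and fold-index values are negative — synthetic dehydrins are hydrophilic
and disordered by construction); `out/games_howell.tsv` the pairwise group
comparisons for the six properties; `out/rejects.tsv` any sequence with no
K segment (by definition not a dehydrin).

The same works for promoters:

```bash
dehydrinscan run-promoters promoters.fa --out-dir out
```

writing `cis_hits.tsv`, `cis_frequency.tsv` (percent of promoters carrying
each element at least once) and a per-promoter category rollup.

From Python, the pieces compose directly:

```python
from dehydrinscan import scan_all_segments, build_profile, biochem_profile

seq = "MAGT" + "EKKGIMDKIKEKLPG" + "GTHGQEDSN" + "EKKGIMDKIKEKLPG" + "GGE"
matches = scan_all_segments(seq)
print(build_profile(seq, matches).formula)          # K2
print(round(biochem_profile(seq).gravy, 3))         # -1.23 (hydrophilic)
```

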