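"""Synthetic dehydrins and promoters with known ground truth.

Every pipeline stage is testable without downloads: this module generates
dehydrin-like proteins (hydrophilic Gly/Thr-rich Φ background with K/Y/S/F
segments planted in a chosen order and copy number) and promoter sequences
with cis-elements planted at known coordinates on either strand, returning
the exact planted coordinates alongside the records.

Segment residues are sampled from the class PSPMs restricted to the
degenerate pattern, so noise-free plants always satisfy the scanner's core
and mismatch rules. Optional mutations touch only non-core positions, so a
mutated plant stays within the default mismatch budget.

Cohort architecture-type weights default to the woody-plant study
conditions: gymnosperm trees dominated by FSKn (56.3%) and FnKn (21%),
angiosperm vines by YnSKn (69.4%), angiosperm trees/shrubs by FSKn (39.5%),
with Y-types absent from gymnosperms and Kn/YnKn/FnKn absent from vines.

All generation is reproducible from (spec, seed); there is no hidden global
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .architecture import expand_formula
from .io_formats import Group, PromoterRecord, ProteinRecord
from .promoter_cis import IUPAC, CisElement, CisHit, reverse_complement, scan_promoter
from .segment_scanner import (
    AA,
    AA_INDEX,
    FixedPattern,
    SegmentClass,
    SerinePattern,
    default_pattern,
    default_pspm,
)


@dataclass(frozen=True)
class PlantedFeature:
    """One planted segment or element with its exact coordinates."""

    name: str            # segment class letter or cis-element name
    start: int
    end: int
    string: str          # the planted string, in its own orientation
    strand: str = "+"    # promoters only; '+' for protein segments


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated record."""

    record_id: str
    features: tuple[PlantedFeature, ...]
    formula: str = ""
    group: str = ""


def load_background_composition() -> tuple[str, np.ndarray]:
    """Φ-background residue alphabet and probabilities from the shipped table."""
    residues, probs = [], []
    text = (resources.files("dehydrinscan") / "data" / "background_composition.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            res, p = line.split("\t")
            residues.append(res)
            probs.append(float(p))
    p = np.asarray(probs)
    return "".join(residues), p / p.sum()


_BG_RESIDUES, _BG_PROBS = load_background_composition()

# modal tract-length distribution for planted S segments (7 Ser most common)
_TRACT_LENGTHS = np.array([4, 5, 6, 7, 8])
_TRACT_PROBS = np.array([0.10, 0.10, 0.15, 0.50, 0.15])

_DEFAULT_TYPE_WEIGHTS: dict[str, dict[str, float]] = {
    Group.GYMNOSPERM_TREE.value: {
        "FSKn": 0.563, "FnKn": 0.210, "Kn": 0.080, "KnS": 0.070, "SKn": 0.077,
    },
    Group.ANGIOSPERM_TREE_SHRUB.value: {
        "FSKn": 0.395, "FnKn": 0.052, "YnSKn": 0.200, "YnKn": 0.065,
        "Kn": 0.100, "KnS": 0.090, "SKn": 0.098,
    },
    Group.ANGIOSPERM_VINE.value: {
        "YnSKn": 0.694, "FSKn": 0.222, "SKn": 0.050, "KnS": 0.034,
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """What a synthetic protein cohort looks like.

    n_per_group: cohort size per taxon group.
    type_weights: architecture-type sampling weights per group (sum to 1).
    mutations_per_segment: non-core substitutions applied to each plant.
    linker_range: Φ-linker length bounds between segments (inclusive).
    seed: mandatory; all randomness derives from it.
    """

    n_per_group: Mapping[str, int]
    seed: int
    type_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_TYPE_WEIGHTS
    )
    mutations_per_segment: int = 0
    linker_range: tuple[int, int] = (10, 60)

    def __post_init__(self) -> None:
        for group, weights in self.type_weights.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"type weights for {group} sum to {total}, not 1")


def sample_background(length: int, rng: np.random.Generator) -> str:
    codes = rng.choice(len(_BG_RESIDUES), size=length, p=_BG_PROBS)
    return "".join(_BG_RESIDUES[c] for c in codes)


def _sample_from_column(col: np.ndarray, allowed: frozenset, rng: np.random.Generator) -> str:
    idx = [AA_INDEX[r] for r in sorted(allowed)]
    p = col[idx]
    return sorted(allowed)[rng.choice(len(idx), p=p / p.sum())]


def sample_segment(
    segment_class: SegmentClass, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """One segment string drawn from the class PSPM under the pattern.

    Returns the string and its non-core position indices (mutation targets).
    For S segments the residue after the tract is drawn from {D, E} so the
    planted tract boundary is unambiguous.
    """
    pattern = default_pattern(segment_class)
    pspm = default_pspm(segment_class)
    if isinstance(pattern, SerinePattern):
        tract_len = int(rng.choice(_TRACT_LENGTHS, p=_TRACT_PROBS))
        chars = [
            _sample_from_column(pspm.probs[i], allowed, rng)
            for i, allowed in enumerate(pattern.anchor)
        ]
        chars.extend("S" * tract_len)
        tail_sets = (frozenset("DE"),) + pattern.tail[1:]
        for j, allowed in enumerate(tail_sets):
            chars.append(_sample_from_column(pspm.probs[12 + j], allowed, rng))
        non_core = list(range(5)) + list(range(5 + tract_len, 5 + tract_len + 4))
        return "".join(chars), non_core
    chars = [
        _sample_from_column(pspm.probs[i], allowed, rng)
        for i, allowed in enumerate(pattern.positions)
    ]
    non_core = [i for i in range(pattern.width) if i not in pattern.core]
    return "".join(chars), non_core


def _mutate(seg: str, non_core: list[int], n_sub: int, rng: np.random.Generator) -> str:
    if n_sub == 0 or not non_core:
        return seg
    chars = list(seg)
    targets = rng.choice(len(non_core), size=min(n_sub, len(non_core)), replace=False)
    for t in targets:
        pos = non_core[int(t)]
        alternatives = [a for a in AA if a != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def synth_dehydrin(
    arch_formula: str,
    rng: np.random.Generator | int,
    record_id: str = "SYN1",
    group: Group = Group.UNASSIGNED,
    mutations_per_segment: int = 0,
    linker_range: tuple[int, int] = (10, 60),
    terminal_range: tuple[int, int] = (5, 30),
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Generate one dehydrin-like protein for an architecture formula.

    The formula ("Y2SK3", "FSK", explicit atypical strings like "KYK") is
    expanded to its letter string; each segment is sampled from its PSPM and
    embedded in Φ-background linkers. The truth carries exact coordinates.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    letters = expand_formula(arch_formula)
    if "K" not in letters:
        raise ValueError(f"formula {arch_formula!r} has no K segment: not a dehydrin")
    parts = [sample_background(int(rng.integers(*terminal_range, endpoint=True)), rng)]
    features = []
    pos = len(parts[0])
    for i, letter in enumerate(letters):
        seg, non_core = sample_segment(SegmentClass(letter), rng)
        seg = _mutate(seg, non_core, mutations_per_segment, rng)
        parts.append(seg)
        features.append(PlantedFeature(letter, pos, pos + len(seg), seg))
        pos += len(seg)
        gap_range = linker_range if i < len(letters) - 1 else terminal_range
        linker = sample_background(int(rng.integers(*gap_range, endpoint=True)), rng)
        parts.append(linker)
        pos += len(linker)
    sequence = "".join(parts)
    record = ProteinRecord(
        accession=record_id,
        description=f"synthetic dehydrin {arch_formula}",
        sequence=sequence,
        group=group,
    )
    truth = SyntheticTruth(
        record_id=record_id,
        features=tuple(features),
        formula=arch_formula,
        group=group.value,
    )
    return record, truth


def _formula_for_type(arch_type: str, rng: np.random.Generator) -> str:
    n_k = int(rng.choice(np.arange(1, 10), p=_geometric_weights(9, 0.6)))
    n_y = int(rng.choice([1, 2, 3], p=[0.70, 0.25, 0.05]))
    n_f = int(rng.choice([1, 2], p=[0.80, 0.20]))
    if arch_type == "Kn":
        return f"K{n_k}"
    if arch_type == "KnS":
        return f"K{n_k}S"
    if arch_type == "SKn":
        return f"SK{n_k}"
    if arch_type == "YnKn":
        return f"Y{n_y}K{n_k}"
    if arch_type == "YnSKn":
        return f"Y{n_y}SK{n_k}"
    if arch_type == "FSKn":
        return f"FSK{n_k}"
    if arch_type == "FnKn":
        return f"F{n_f}K{n_k}"
    raise ValueError(f"cannot draw a formula for type {arch_type!r}")


def _geometric_weights(n: int, ratio: float) -> np.ndarray:
    w = ratio ** np.arange(n)
    return w / w.sum()


def synth_cohort(spec: CohortSpec) -> tuple[list[ProteinRecord], list[SyntheticTruth]]:
    """Generate a cohort with the spec's per-group sizes and type weights."""
    rng = np.random.default_rng(spec.seed)
    group_enum = {g.value: g for g in Group}
    records, truths = [], []
    counter = 0
    for group_name, n in spec.n_per_group.items():
        weights = spec.type_weights[group_name]
        types = list(weights)
        probs = np.array([weights[t] for t in types])
        for _ in range(n):
            counter += 1
            arch_type = types[int(rng.choice(len(types), p=probs))]
            formula = _formula_for_type(arch_type, rng)
            rec, truth = synth_dehydrin(
                formula,
                rng,
                record_id=f"SYN{counter:05d}",
                group=group_enum.get(group_name, Group.UNASSIGNED),
                mutations_per_segment=spec.mutations_per_segment,
                linker_range=spec.linker_range,
            )
            records.append(rec)
            truths.append(truth)
    return records, truths


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantingPlan:
    """One element to plant: name, consensus, start, strand."""

    name: str
    consensus: str
    start: int
    strand: str = "+"


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in consensus
    )


def synth_promoter(
    length: int,
    plan: Sequence[PlantingPlan],
    rng: np.random.Generator | int,
    gene_id: str = "SYNP1",
    catalog: Sequence[CisElement] | None = None,
    max_scrub_rounds: int = 500,
) -> tuple[PromoterRecord, SyntheticTruth]:
    """Uniform-ACGT promoter with elements planted per plan.

    Plan intervals must fit and not overlap. A '-' plant inserts the reverse
    complement of the realized element into the forward sequence. When a
    catalog is given, background positions are resampled until the only
    catalog hits are the planted ones (chance background matches are
    scrubbed); a spurious hit nested entirely inside planted intervals cannot
    be scrubbed and raises ValueError.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    intervals = []
    for p in plan:
        end = p.start + len(p.consensus)
        if p.start < 0 or end > length:
            raise ValueError(f"plant {p.name} at {p.start} does not fit in length {length}")
        intervals.append((p.start, end))
    for (s1, e1), (s2, e2) in zip(sorted(intervals), sorted(intervals)[1:]):
        if e1 > s2:
            raise ValueError("planting plan intervals overlap")
    seq = list("".join("ACGT"[c] for c in rng.integers(4, size=length)))
    features = []
    planted_cover = set()
    for p in plan:
        realized = _realize_consensus(p.consensus.upper(), rng)
        insert = realized if p.strand == "+" else reverse_complement(realized)
        end = p.start + len(insert)
        seq[p.start : end] = insert
        features.append(PlantedFeature(p.name, p.start, end, realized, p.strand))
        planted_cover.update(range(p.start, end))
    if catalog is not None:
        expected = {(f.name, f.start, f.end) for f in features}
        for _ in range(max_scrub_rounds):
            record = PromoterRecord(gene_id=gene_id, sequence="".join(seq))
            spurious = [
                h
                for h in scan_promoter(record, catalog)
                if (h.element, h.start, h.end) not in expected
            ]
            if not spurious:
                break
            hit = spurious[0]
            free = [i for i in range(hit.start, hit.end) if i not in planted_cover]
            if not free:
                raise ValueError(
                    f"spurious {hit.element} hit at {hit.start} lies inside planted "
                    "elements and cannot be scrubbed"
                )
            i = free[int(rng.integers(len(free)))]
            seq[i] = "ACGT"[int(rng.integers(4))]
        else:
            raise RuntimeError("background scrubbing did not converge")
    record = PromoterRecord(gene_id=gene_id, sequence="".join(seq))
    truth = SyntheticTruth(record_id=gene_id, features=tuple(features))
    return record, truth


def synth_promoter_set(
    n: int,
    length: int,
    elements: Sequence[CisElement],
    incidence: Mapping[str, float],
    rng: np.random.Generator | int,
    catalog: Sequence[CisElement] | None = None,
) -> tuple[list[PromoterRecord], list[SyntheticTruth], dict[str, set[str]]]:
    """A promoter set with exact per-element incidence.

    Each element is planted in round(incidence * n) promoters chosen at
    random, at random non-overlapping positions and random strands. Returns
    records, truths and the element -> {gene_id} incidence map.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    plans: dict[int, list[PlantingPlan]] = {i: [] for i in range(n)}
    incidence_map: dict[str, set[str]] = {}
    gene_ids = [f"SYNP{i + 1:03d}" for i in range(n)]
    for element in elements:
        frac = incidence.get(element.name, 0.0)
        count = int(round(frac * n))
        chosen = rng.choice(n, size=count, replace=False) if count else []
        incidence_map[element.name] = {gene_ids[int(i)] for i in chosen}
        for i in chosen:
            consensus = element.consensus[int(rng.integers(len(element.consensus)))]
            taken = [(p.start, p.start + len(p.consensus)) for p in plans[int(i)]]
            for _ in range(1000):
                start = int(rng.integers(0, length - len(consensus) + 1))
                end = start + len(consensus)
                if all(end <= s or start >= e for s, e in taken):
                    break
            else:
                raise RuntimeError("could not place element without overlap")
            strand = "+" if rng.random() < 0.5 else "-"
            plans[int(i)].append(PlantingPlan(element.name, consensus, start, strand))
    records, truths = [], []
    for i in range(n):
        rec, truth = synth_promoter(
            length, plans[i], rng, gene_id=gene_ids[i], catalog=catalog
        )
        records.append(rec)
        truths.append(truth)
    return records, truths, incidence_map
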