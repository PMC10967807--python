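"""Dehydrin architecture typing and rare-motif census.

The ordered combination of Y/S/K/F segments defines a dehydrin's
architectural type. Seven canonical types occur in seed plants — Kn, KnS,
SKn, YnKn, YnSKn, FSKn and FnKn — and anything else (Y after K, S inside the
K block, F together with Y, ...) is atypical. The K segment is obligatory:
a sequence without one is not a dehydrin.

Rare sequence motifs tallied here: K segments flanked by His-His on both
sides (pH-dependent membrane binding), the poly-lysine motif KKKKKEKK
(polar zipper), His-His-rich sequences (four or more HH dimers,
metal binding) and the HH-X3-HH metal-binding motif HHSGDHH.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .segment_scanner import SegmentClass, SegmentMatch

logger = logging.getLogger("dehydrinscan")


class ArchitectureType(Enum):
    Kn = "Kn"
    KnS = "KnS"
    SKn = "SKn"
    YnKn = "YnKn"
    YnSKn = "YnSKn"
    FSKn = "FSKn"
    FnKn = "FnKn"
    ATYPICAL = "atypical"


# Grammar of the seven canonical names, tried in order; first match wins.
_GRAMMAR: tuple[tuple[re.Pattern, ArchitectureType], ...] = (
    (re.compile(r"^K+$"), ArchitectureType.Kn),
    (re.compile(r"^SK+$"), ArchitectureType.SKn),
    (re.compile(r"^K+S$"), ArchitectureType.KnS),
    (re.compile(r"^Y+K+$"), ArchitectureType.YnKn),
    (re.compile(r"^Y+SK+$"), ArchitectureType.YnSKn),
    (re.compile(r"^FSK+$"), ArchitectureType.FSKn),
    (re.compile(r"^F+K+$"), ArchitectureType.FnKn),
)


@dataclass(frozen=True)
class RareMotifFlags:
    """Rare-motif census for one sequence."""

    hh_flanked_k: tuple[int, ...]  # indices of K matches with HH on both sides
    poly_k: bool                   # exact KKKKKEKK
    hh_count: int                  # non-overlapping HH occurrences
    hh_rich: bool                  # hh_count >= 4
    hh_x3_hh: bool                 # HHSGDHH
    poly_k_relaxed: int = 0        # diagnostic: K{4,}EK{1,3} occurrences
    one_sided_hh_k: tuple[int, ...] = ()  # diagnostic: HH on exactly one side


@dataclass(frozen=True)
class ArchitectureProfile:
    """Ordered segment string, counts, canonical type and rare-motif flags."""

    ordered_letters: str
    n_k: int
    n_y: int
    n_s: int
    n_f: int
    arch_type: ArchitectureType
    formula: str
    rare: RareMotifFlags | None = None


class NoKSegmentError(ValueError):
    """Raised for sequences without a K segment (not dehydrins)."""


def architecture_string(matches: Sequence[SegmentMatch]) -> tuple[str, str]:
    """Ordered letter string and run-compressed formula from resolved matches.

    Letters follow ascending start coordinate; the formula compresses maximal
    runs ("YYSKKK" -> "Y2SK3"), omitting the digit for single copies.
    """
    if not matches:
        raise NoKSegmentError("no segment matches: cannot build an architecture")
    ordered = sorted(matches, key=lambda m: m.start)
    letters = "".join(m.segment_class.value for m in ordered)
    if "K" not in letters:
        raise NoKSegmentError("no K segment: sequence is not a dehydrin")
    return letters, compress_formula(letters)


def compress_formula(letters: str) -> str:
    parts = []
    for run in re.finditer(r"(.)\1*", letters):
        n = len(run.group(0))
        parts.append(run.group(1) + (str(n) if n > 1 else ""))
    return "".join(parts)


def expand_formula(formula: str) -> str:
    """Inverse of :func:`compress_formula`: "Y2SK3" -> "YYSKKK"."""
    if not re.fullmatch(r"(?:[KYSF]\d*)+", formula):
        raise ValueError(f"not a segment formula: {formula!r}")
    out = []
    for m in re.finditer(r"([KYSF])(\d*)", formula):
        out.append(m.group(1) * (int(m.group(2)) if m.group(2) else 1))
    return "".join(out)


def classify_architecture(ordered_letters: str) -> ArchitectureType:
    """Map an ordered letter string onto one of the seven types or atypical.

    FSKn is read strictly (exactly one F, one S); interleavings such as
    Y-after-K or multiple S blocks are atypical, mirroring how unusual
    architectures are set aside rather than forced into a named type.
    """
    if not ordered_letters or set(ordered_letters) - set("KYSF"):
        raise ValueError(f"letters must be a non-empty string over KYSF: {ordered_letters!r}")
    if "K" not in ordered_letters:
        raise NoKSegmentError("no K segment: sequence is not a dehydrin")
    for pattern, arch in _GRAMMAR:
        if pattern.match(ordered_letters):
            return arch
    return ArchitectureType.ATYPICAL


def detect_rare_motifs(sequence: str, k_matches: Sequence[SegmentMatch]) -> RareMotifFlags:
    """Census of the rare motifs in one sequence.

    ``k_matches`` are the sequence's resolved K-segment matches; a K segment
    counts as HH-flanked only when both the two residues immediately before
    and the two immediately after it are His-His. HH occurrences are counted
    non-overlapping.
    """
    sequence = sequence.upper()
    flanked, one_sided = [], []
    for idx, m in enumerate(k_matches):
        if m.segment_class is not SegmentClass.K:
            continue
        left = m.start >= 2 and sequence[m.start - 2 : m.start] == "HH"
        right = sequence[m.end : m.end + 2] == "HH"
        if left and right:
            flanked.append(idx)
        elif left or right:
            one_sided.append(idx)
    if one_sided:
        logger.info("K segment(s) %s flanked by HH on one side only", one_sided)
    hh_count = sequence.count("HH")  # non-overlapping by str.count semantics
    return RareMotifFlags(
        hh_flanked_k=tuple(flanked),
        poly_k="KKKKKEKK" in sequence,
        hh_count=hh_count,
        hh_rich=hh_count >= 4,
        hh_x3_hh="HHSGDHH" in sequence,
        poly_k_relaxed=len(re.findall(r"K{4,}EK{1,3}", sequence)),
        one_sided_hh_k=tuple(one_sided),
    )


def build_profile(sequence: str, matches: Sequence[SegmentMatch]) -> ArchitectureProfile:
    """Full architecture profile from a sequence's resolved matches."""
    letters, formula = architecture_string(matches)
    counts = Counter(letters)
    k_matches = [m for m in sorted(matches, key=lambda m: m.start) if m.segment_class is SegmentClass.K]
    return ArchitectureProfile(
        ordered_letters=letters,
        n_k=counts.get("K", 0),
        n_y=counts.get("Y", 0),
        n_s=counts.get("S", 0),
        n_f=counts.get("F", 0),
        arch_type=classify_architecture(letters),
        formula=formula,
        rare=detect_rare_motifs(sequence, k_matches),
    )


def type_distribution(
    profiles: Sequence[ArchitectureProfile], groups: Sequence[str]
) -> pd.DataFrame:
    """Percentage of each architecture type within each group.

    Rows are groups, columns the architecture types; each row sums to 100.
    Empty groups are omitted with a warning.
    """
    if len(profiles) != len(groups):
        raise ValueError("one group label per profile required")
    df = pd.DataFrame(
        {"group": list(groups), "arch_type": [p.arch_type.value for p in profiles]}
    )
    seen = set(df["group"])
    for g in set(groups) - seen:
        logger.warning("group %s has no profiles; omitted", g)
    table = pd.crosstab(df["group"], df["arch_type"])
    table = table.reindex(columns=[t.value for t in ArchitectureType], fill_value=0)
    return 100.0 * table.div(table.sum(axis=1), axis=0)
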