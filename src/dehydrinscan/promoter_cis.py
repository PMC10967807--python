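"""Promoter cis-regulatory element scanning and presence profiling.

Scans promoter sequences against a catalog of named cis-elements given as
IUPAC consensus strings (PlantCARE-style exact matching, no scoring), on both
strands, and reports per-element presence frequencies: the percentage of
promoters containing the element at least once — the quantity usually shown
as a bar per element.

Conventions: hit coordinates are 0-based half-open on the input (forward)
sequence; ``strand`` is '+' or '-'; ``matched_seq`` is read in the strand's
orientation, so it always satisfies the consensus as written. N in a
promoter matches nothing, including the IUPAC wildcard N.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import PromoterRecord

logger = logging.getLogger("dehydrinscan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class CisCategory(Enum):
    LIGHT = "LIGHT"
    HORMONE = "HORMONE"
    STRESS = "STRESS"
    DEVELOPMENT = "DEVELOPMENT"


@dataclass(frozen=True)
class CisElement:
    """One catalog entry: element name, functional category, consensus variants."""

    name: str
    category: CisCategory
    consensus: tuple[str, ...]


@dataclass(frozen=True)
class CisHit:
    """One located element occurrence in a promoter."""

    gene_id: str
    element: str
    start: int
    end: int
    strand: str
    matched_seq: str


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(consensus: str) -> re.Pattern:
    # plain ACGT classes only: promoter N never matches
    return re.compile("".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in consensus))


def _validate_consensus(consensus: str, context: str) -> None:
    if not consensus:
        raise ValueError(f"{context}: empty consensus")
    for ch in consensus:
        if ch not in IUPAC:
            raise ValueError(f"{context}: illegal IUPAC letter {ch!r}")


def default_catalog_path() -> Path:
    return Path(str(resources.files("dehydrinscan") / "data" / "cis_catalog.tsv"))


def load_catalog(path: str | Path | None = None) -> list[CisElement]:
    """Load a cis-element catalog TSV (name, category, comma-separated consensi).

    Duplicate names and non-IUPAC letters are errors; an empty catalog is
    allowed with a warning.
    """
    path = default_catalog_path() if path is None else Path(path)
    elements: list[CisElement] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        name, category, consensi = (p.strip() for p in parts)
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate element name {name!r}")
        seen.add(name)
        variants = tuple(v.strip().upper() for v in consensi.split(",") if v.strip())
        for v in variants:
            _validate_consensus(v, f"{path}:{lineno} ({name})")
        elements.append(CisElement(name, CisCategory(category), variants))
    if not elements:
        logger.warning("catalog %s is empty", path)
    return elements


def scan_promoter(promoter: PromoterRecord, catalog: Sequence[CisElement]) -> list[CisHit]:
    """All element occurrences in one promoter, both strands, sorted by start.

    Overlapping occurrences are all reported. A '-' hit at forward
    coordinates [start, end) means the element reads 5'→3' on the reverse
    strand; its ``matched_seq`` is the reverse complement of the forward
    slice.
    """
    seq = promoter.sequence.upper()
    hits: list[CisHit] = []
    for element in catalog:
        for consensus in element.consensus:
            for strand, pattern_str in (("+", consensus), ("-", reverse_complement(consensus))):
                regex = re.compile(f"(?=({_iupac_regex(pattern_str).pattern}))")
                for m in regex.finditer(seq):
                    start, end = m.start(1), m.end(1)
                    matched = seq[start:end] if strand == "+" else reverse_complement(seq[start:end])
                    hits.append(CisHit(promoter.gene_id, element.name, start, end, strand, matched))
    # palindromic consensi produce identical +/- loci; keep both (presence is
    # per promoter, so counts stay correct) but drop exact duplicates
    hits = sorted(set(hits), key=lambda h: (h.start, h.end, h.element, h.strand))
    return hits


def scan_promoters(
    promoters: Sequence[PromoterRecord], catalog: Sequence[CisElement]
) -> dict[str, list[CisHit]]:
    """Scan every promoter; mapping gene_id -> hits."""
    return {p.gene_id: scan_promoter(p, catalog) for p in promoters}


def presence_frequency(
    hits_by_promoter: Mapping[str, Sequence[CisHit]],
    catalog: Sequence[CisElement],
) -> pd.DataFrame:
    """Per-element presence profile over the promoter set.

    Columns: element, category, promoters_with_hit, total_promoters, percent
    (one decimal). Presence is per promoter: multiple hits count once.
    """
    total = len(hits_by_promoter)
    rows = []
    for element in catalog:
        with_hit = sum(
            1
            for hits in hits_by_promoter.values()
            if any(h.element == element.name for h in hits)
        )
        percent = round(100.0 * with_hit / total, 1) if total else 0.0
        rows.append(
            {
                "element": element.name,
                "category": element.category.value,
                "promoters_with_hit": with_hit,
                "total_promoters": total,
                "percent": percent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["element", "category", "promoters_with_hit", "total_promoters", "percent"],
    )


def meja_presence(hits_by_promoter: Mapping[str, Sequence[CisHit]]) -> float:
    """Percent of promoters with a MeJA-responsive element.

    Union presence of the CGTCA-motif and TGACG-motif (the two strands of the
    same MeJA-responsive element are catalogued under their own names).
    """
    total = len(hits_by_promoter)
    if not total:
        return 0.0
    with_hit = sum(
        1
        for hits in hits_by_promoter.values()
        if any(h.element in ("CGTCA-motif", "TGACG-motif") for h in hits)
    )
    return round(100.0 * with_hit / total, 1)


def category_rollup(
    hits_by_promoter: Mapping[str, Sequence[CisHit]], catalog: Sequence[CisElement]
) -> pd.DataFrame:
    """Per-promoter counts of hits in each functional category."""
    cat_of = {e.name: e.category.value for e in catalog}
    rows = []
    for gene_id, hits in hits_by_promoter.items():
        row = {"gene_id": gene_id}
        for cat in CisCategory:
            row[cat.value.lower()] = sum(1 for h in hits if cat_of.get(h.element) == cat.value)
        rows.append(row)
    return pd.DataFrame(rows)
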