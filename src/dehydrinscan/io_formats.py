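"""Input/output for the dehydrin pipeline.

Reads protein and promoter FASTA files into validated records, reads the
accession→taxon-group table, and writes the tabular/JSON reports the other
stages produce.

All coordinates written by this package are 0-based, half-open; every report
header says so.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("dehydrinscan")

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

COORDINATE_NOTE = "coordinates are 0-based, half-open"


class Group(Enum):
    """Taxon group of a dehydrin sequence."""

    GYMNOSPERM_TREE = "gymnosperm_tree"
    ANGIOSPERM_TREE_SHRUB = "angiosperm_tree_shrub"
    ANGIOSPERM_VINE = "angiosperm_vine"
    UNASSIGNED = "unassigned"


class FastaParseError(ValueError):
    """Raised when a FASTA entry violates the record contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its taxon-group label."""

    accession: str
    description: str
    sequence: str
    group: Group = Group.UNASSIGNED

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence, PROTEIN_ALPHABET, self.accession)


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter (upstream DNA) sequence."""

    gene_id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence, DNA_ALPHABET, self.gene_id)


def _validate_sequence(seq: str, alphabet: frozenset, name: str) -> None:
    if not seq:
        raise FastaParseError(f"record {name!r}: empty sequence")
    for pos, letter in enumerate(seq):
        if letter not in alphabet:
            raise FastaParseError(
                f"record {name!r}: illegal letter {letter!r} at position {pos}"
            )


def read_group_table(path: str | Path) -> dict[str, Group]:
    """Read a 2-column TSV (accession, group token) into a mapping.

    Tokens must be Group values (case-insensitive); an unknown token is an
    error, a duplicated accession is an error.
    """
    mapping: dict[str, Group] = {}
    tokens = {g.value: g for g in Group}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            accession, token = parts[0].strip(), parts[1].strip().lower()
            if token not in tokens:
                raise ValueError(
                    f"{path}:{lineno}: unknown group token {parts[1]!r}; "
                    f"expected one of {sorted(tokens)}"
                )
            if accession in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate accession {accession!r}")
            mapping[accession] = tokens[token]
    return mapping


def read_fasta_proteins(
    path: str | Path, group_table: Mapping[str, Group] | None = None
) -> list[ProteinRecord]:
    """Parse a protein FASTA file, preserving entry order.

    Sequences are uppercased; letters outside the 20 canonical residues plus X
    raise :class:`FastaParseError` naming the record and position. When a
    group table is given, accessions missing from it fall back to UNASSIGNED
    with a logged warning.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        group = Group.UNASSIGNED
        if group_table is not None:
            if entry.id in group_table:
                group = group_table[entry.id]
            else:
                logger.warning("accession %s missing from group table; UNASSIGNED", entry.id)
        records.append(
            ProteinRecord(
                accession=entry.id,
                description=entry.description,
                sequence=seq,
                group=group,
            )
        )
    return records


def read_fasta_dna(path: str | Path) -> list[PromoterRecord]:
    """Parse a promoter DNA FASTA file (A/C/G/T/N; uppercased on read)."""
    records: list[PromoterRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(
            PromoterRecord(gene_id=entry.id, sequence=str(entry.seq).upper())
        )
    return records


def write_fasta(records: Iterable[ProteinRecord | PromoterRecord], path: str | Path) -> None:
    """Write records back to FASTA (identifier + sequence round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            name = rec.accession if isinstance(rec, ProteinRecord) else rec.gene_id
            fh.write(f">{name}\n{rec.sequence}\n")


def write_report(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    fmt: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write a per-sequence report as TSV or JSON with a stable column order.

    TSV output starts with a comment line documenting the coordinate
    convention. JSON output is a list of row objects and round-trips through
    :func:`read_report`.
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    if fmt == "tsv":
        df = pd.DataFrame(list(rows), columns=list(columns))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {COORDINATE_NOTE}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif fmt == "json":
        payload = {"coordinate_convention": COORDINATE_NOTE, "rows": [dict(r) for r in rows]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}; use 'tsv' or 'json'")


def read_report(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", comment="#")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["rows"])
    raise ValueError(f"unknown report format {fmt!r}; use 'tsv' or 'json'")


def deduplicate(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop records whose exact sequence was already seen (first kept)."""
    seen: set[str] = set()
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out
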