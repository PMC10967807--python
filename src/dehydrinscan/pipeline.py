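"""End-to-end orchestration of the dehydrin analysis stages.

The protein pipeline composes: FASTA in → segment scan → K-segment filter
(no K segment ⇒ not a dehydrin ⇒ rejects file) → architecture typing and
rare-motif census → biochemical profiles → per-group summaries and
Games–Howell pairwise comparisons. The promoter pipeline composes: FASTA +
catalog → cis-element scan → presence-frequency profile → category rollup.

Every stage writes the documented TSVs so stages can be re-run or mixed
with external tools; a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .architecture import ArchitectureProfile, build_profile, type_distribution
from .biochem import biochem_profile
from .group_stats import games_howell, summarize_groups
from .io_formats import (
    COORDINATE_NOTE,
    Group,
    ProteinRecord,
    deduplicate,
    read_fasta_dna,
    read_fasta_proteins,
    read_group_table,
)
from .promoter_cis import (
    category_rollup,
    load_catalog,
    meja_presence,
    presence_frequency,
    scan_promoters,
)
from .segment_scanner import ScanParams, SegmentClass, scan_all_segments

logger = logging.getLogger("dehydrinscan")

BIOCHEM_PROPERTIES = ("mw", "pi", "gravy", "fold_index", "lys_pct", "his_pct")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run; echoed into the output dir."""

    out_dir: str
    proteins: str | None = None
    group_table: str | None = None
    promoters: str | None = None
    catalog: str | None = None
    mismatch_budget: int = 2
    score_threshold: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def scan_params(self) -> ScanParams:
        return ScanParams(
            mismatch_budget=self.mismatch_budget, score_threshold=self.score_threshold
        )

    def to_text(self) -> str:
        lines = [f"{k}={v}" for k, v in asdict(self).items()]
        return "\n".join(lines) + "\n"

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def _echo_config(config: RunConfig, out: Path) -> None:
    (out / "run_config.txt").write_text(config.to_text(), encoding="utf-8")
    logger.info(
        "dehydrinscan %s | config %s | seed %d",
        __version__, config.config_hash(), config.seed,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {COORDINATE_NOTE}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_protein_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the protein stages; returns the written report paths.

    Sequences with no K segment are excluded from every downstream table and
    listed in ``rejects.tsv`` (the obligatory-K filter, kept auditable).
    """
    if config.proteins is None:
        raise ValueError("config.proteins is required for the protein pipeline")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        groups = read_group_table(config.group_table) if config.group_table else None
        records = read_fasta_proteins(config.proteins, groups)
        n_in = len(records)
        records = deduplicate(records)
        if len(records) < n_in:
            logger.info("removed %d exact-duplicate sequences", n_in - len(records))
        params = config.scan_params()

        segment_rows, arch_rows, biochem_rows, reject_rows = [], [], [], []
        profiles: list[ArchitectureProfile] = []
        kept: list[ProteinRecord] = []
        for rec in records:
            matches = scan_all_segments(rec.sequence, params)
            k_matches = [m for m in matches if m.segment_class is SegmentClass.K]
            if not k_matches:
                reject_rows.append(
                    {"accession": rec.accession, "length": len(rec.sequence),
                     "reason": "no K segment"}
                )
                continue
            kept.append(rec)
            for m in matches:
                segment_rows.append(
                    {"accession": rec.accession, "class": m.segment_class.value,
                     "start": m.start, "end": m.end, "matched_seq": m.matched_seq,
                     "score": round(m.score, 4)}
                )
            profile = build_profile(rec.sequence, matches)
            profiles.append(profile)
            arch_rows.append(
                {"accession": rec.accession, "group": rec.group.value,
                 "formula": profile.formula, "arch_type": profile.arch_type.value,
                 "nK": profile.n_k, "nY": profile.n_y, "nS": profile.n_s,
                 "nF": profile.n_f,
                 "hh_flanked_k": len(profile.rare.hh_flanked_k),
                 "poly_k": profile.rare.poly_k, "hh_count": profile.rare.hh_count,
                 "hh_rich": profile.rare.hh_rich, "hh_x3_hh": profile.rare.hh_x3_hh}
            )
            bp = biochem_profile(rec.sequence)
            biochem_rows.append(
                {"accession": rec.accession, "group": rec.group.value,
                 "length": bp.length, "mw": round(bp.mw, 2), "pi": round(bp.pi, 3),
                 "gravy": round(bp.gravy, 4), "fold_index": round(bp.fold_index, 4),
                 "lys_pct": round(bp.lys_pct, 2), "his_pct": round(bp.his_pct, 2)}
            )

        _write_tsv(pd.DataFrame(segment_rows,
                                columns=["accession", "class", "start", "end",
                                         "matched_seq", "score"]),
                   out / "segments.tsv")
        written["segments"] = out / "segments.tsv"
        _write_tsv(pd.DataFrame(arch_rows,
                                columns=["accession", "group", "formula", "arch_type",
                                         "nK", "nY", "nS", "nF", "hh_flanked_k",
                                         "poly_k", "hh_count", "hh_rich", "hh_x3_hh"]),
                   out / "architecture.tsv")
        written["architecture"] = out / "architecture.tsv"
        _write_tsv(pd.DataFrame(biochem_rows,
                                columns=["accession", "group", "length", "mw", "pi",
                                         "gravy", "fold_index", "lys_pct", "his_pct"]),
                   out / "biochem.tsv")
        written["biochem"] = out / "biochem.tsv"
        _write_tsv(pd.DataFrame(reject_rows, columns=["accession", "length", "reason"]),
                   out / "rejects.tsv")
        written["rejects"] = out / "rejects.tsv"

        labelled = [p for p, r in zip(profiles, kept) if r.group is not Group.UNASSIGNED]
        labels = [r.group.value for r in kept if r.group is not Group.UNASSIGNED]
        if labelled:
            dist = type_distribution(labelled, labels).reset_index()
            _write_tsv(dist, out / "type_distribution.tsv")
            written["type_distribution"] = out / "type_distribution.tsv"

        bio_df = pd.DataFrame(biochem_rows)
        if not bio_df.empty:
            grouped = bio_df[bio_df["group"] != Group.UNASSIGNED.value]
            stats_rows, summary_rows = [], []
            for prop in BIOCHEM_PROPERTIES:
                values = {
                    g: sub[prop].to_numpy()
                    for g, sub in grouped.groupby("group")
                    if len(sub) >= 2
                }
                for s in summarize_groups(values) if values else []:
                    summary_rows.append(
                        {"property": prop, "group": s.group, "n": s.n,
                         "min": s.minimum, "q1": s.q1, "median": s.median,
                         "q3": s.q3, "max": s.maximum}
                    )
                if len(values) >= 2:
                    for r in games_howell(values):
                        stats_rows.append(
                            {"property": prop, "pair": f"{r.group_a} vs {r.group_b}",
                             "mean_diff": round(r.mean_diff, 4), "se": round(r.se, 4),
                             "df": round(r.welch_df, 2), "q": round(r.q_statistic, 4),
                             "p": round(r.p_value, 6), "significant": r.significant}
                        )
            if summary_rows:
                _write_tsv(pd.DataFrame(summary_rows), out / "group_summaries.tsv")
                written["group_summaries"] = out / "group_summaries.tsv"
            if stats_rows:
                _write_tsv(pd.DataFrame(stats_rows), out / "games_howell.tsv")
                written["games_howell"] = out / "games_howell.tsv"
        _echo_config(config, out)
        return written
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise


def run_promoter_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the promoter stages; returns the written report paths."""
    if config.promoters is None:
        raise ValueError("config.promoters is required for the promoter pipeline")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        catalog = load_catalog(config.catalog)
        promoters = read_fasta_dna(config.promoters)
        hits_by_promoter = scan_promoters(promoters, catalog)
        hit_rows = [
            {"gene_id": h.gene_id, "element": h.element, "start": h.start,
             "end": h.end, "strand": h.strand, "matched_seq": h.matched_seq}
            for hits in hits_by_promoter.values()
            for h in hits
        ]
        _write_tsv(pd.DataFrame(hit_rows,
                                columns=["gene_id", "element", "start", "end",
                                         "strand", "matched_seq"]),
                   out / "cis_hits.tsv")
        written["cis_hits"] = out / "cis_hits.tsv"
        profile = presence_frequency(hits_by_promoter, catalog)
        _write_tsv(profile, out / "cis_frequency.tsv")
        written["cis_frequency"] = out / "cis_frequency.tsv"
        rollup = category_rollup(hits_by_promoter, catalog)
        _write_tsv(rollup, out / "cis_category_rollup.tsv")
        written["cis_category_rollup"] = out / "cis_category_rollup.tsv"
        logger.info("MeJA-responsive union presence: %.1f%%", meja_presence(hits_by_promoter))
        _echo_config(config, out)
        return written
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
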