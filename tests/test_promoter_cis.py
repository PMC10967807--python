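import numpy as np
import pytest

from dehydrinscan.io_formats import PromoterRecord
from dehydrinscan.promoter_cis import (
    CisCategory,
    CisElement,
    load_catalog,
    meja_presence,
    presence_frequency,
    reverse_complement,
    scan_promoter,
    scan_promoters,
)
from dehydrinscan.synthetic_data import PlantingPlan, synth_promoter, synth_promoter_set

GBOX = CisElement("G-box", CisCategory.LIGHT, ("CACGTG",))
AUXRR = CisElement("AuxRR-core", CisCategory.HORMONE, ("GGTCCAT",))


class TestCatalog:
    def test_shipped_catalog_loads(self):
        catalog = load_catalog()
        names = [e.name for e in catalog]
        assert len(names) == len(set(names))
        for expected in ("G-box", "Box 4", "ABRE", "CGTCA-motif", "TGACG-motif",
                         "LTR", "DRE core", "W box", "MYB", "MYC", "circadian"):
            assert expected in names
        assert all(e.consensus for e in catalog)

    def test_single_row(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("G-box\tLIGHT\tCACGTG\n")
        catalog = load_catalog(p)
        assert len(catalog) == 1
        assert catalog[0].consensus == ("CACGTG",)

    def test_bad_iupac_letter(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("bad\tLIGHT\tCAJGT\n")
        with pytest.raises(ValueError, match="'J'"):
            load_catalog(p)

    def test_duplicate_name(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("G-box\tLIGHT\tCACGTG\nG-box\tLIGHT\tGACGTG\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_catalog(p)

    def test_empty_catalog_allowed(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("# nothing\n")
        assert load_catalog(p) == []


class TestScanPromoter:
    def test_planted_forward_hit(self):
        seq = "A" * 412 + "CACGTG" + "A" * (2000 - 412 - 6)
        hits = scan_promoter(PromoterRecord("p1", seq), [GBOX])
        strands = {(h.start, h.strand) for h in hits}
        assert (412, "+") in strands
        assert all(h.start == 412 and h.end == 418 for h in hits)

    def test_planted_reverse_hit(self):
        elem = CisElement("W box", CisCategory.STRESS, ("TTGACC",))
        seq = "A" * 100 + reverse_complement("TTGACC") + "A" * 100
        hits = scan_promoter(PromoterRecord("p1", seq), [elem])
        assert [(h.start, h.strand, h.matched_seq) for h in hits] == [(100, "-", "TTGACC")]

    def test_all_n_promoter_no_hits(self):
        elem = CisElement("any", CisCategory.STRESS, ("NNNN",))
        assert scan_promoter(PromoterRecord("p1", "N" * 50), [elem]) == []

    def test_palindrome_paired_strands(self):
        seq = "T" * 30 + "CACGTG" + "T" * 30
        hits = scan_promoter(PromoterRecord("p1", seq), [GBOX])
        assert {(h.start, h.strand) for h in hits} == {(30, "+"), (30, "-")}

    def test_overlapping_occurrences_reported(self):
        elem = CisElement("AA", CisCategory.LIGHT, ("AA",))
        hits = scan_promoter(PromoterRecord("p1", "GAAAG"), [elem])
        plus = [h.start for h in hits if h.strand == "+"]
        assert plus == [1, 2]

    def test_iupac_degeneracy(self):
        elem = CisElement("circ", CisCategory.DEVELOPMENT, ("CAANNNNATC",))
        seq = "G" * 10 + "CAAGCTGATC" + "G" * 10
        hits = scan_promoter(PromoterRecord("p1", seq), [elem])
        assert any(h.start == 10 and h.strand == "+" for h in hits)


class TestPresenceFrequency:
    def test_33_of_34(self, rng):
        records, _, inc = synth_promoter_set(
            34, 400, [AUXRR], {"AuxRR-core": 33 / 34}, rng, catalog=[AUXRR]
        )
        profile = presence_frequency(scan_promoters(records, [AUXRR]), [AUXRR])
        row = profile.iloc[0]
        assert row["promoters_with_hit"] == 33
        assert row["percent"] == 97.1

    def test_absent_everywhere(self):
        records = [PromoterRecord(f"p{i}", "T" * 100) for i in range(5)]
        profile = presence_frequency(scan_promoters(records, [GBOX]), [GBOX])
        assert profile.iloc[0]["percent"] == 0.0

    def test_planted_in_all(self):
        seq = "T" * 20 + "CACGTG" + "T" * 20
        records = [PromoterRecord(f"p{i}", seq) for i in range(4)]
        profile = presence_frequency(scan_promoters(records, [GBOX]), [GBOX])
        assert profile.iloc[0]["percent"] == 100.0

    def test_meja_union(self):
        cgtca = CisElement("CGTCA-motif", CisCategory.HORMONE, ("CGTCA",))
        tgacg = CisElement("TGACG-motif", CisCategory.HORMONE, ("TGACG",))
        records = [
            PromoterRecord("p1", "TT" + "CGTCA" + "TT"),
            PromoterRecord("p2", "TT" * 5),
        ]
        hits = scan_promoters(records, [cgtca, tgacg])
        # CGTCA on + is TGACG on -, so p1 carries both names; union is still 1/2
        assert meja_presence(hits) == 50.0


def test_strand_symmetry_invariant(rng):
    """Reverse-complementing every promoter leaves the profile unchanged."""
    catalog = load_catalog()
    records = [
        PromoterRecord(f"p{i}", "".join("ACGT"[c] for c in rng.integers(4, size=800)))
        for i in range(6)
    ]
    flipped = [PromoterRecord(r.gene_id, reverse_complement(r.sequence)) for r in records]
    prof_fwd = presence_frequency(scan_promoters(records, catalog), catalog)
    prof_rev = presence_frequency(scan_promoters(flipped, catalog), catalog)
    assert prof_fwd.equals(prof_rev)


def test_planted_recovery_equals_incidence(rng):
    """With a scrubbed background, presence equals the planting plan exactly."""
    catalog = load_catalog()
    sub = [e for e in catalog if e.name in
           {"Box 4", "AuxRR-core", "P-box", "GARE-motif", "LTR", "W box"}]
    incidence = {"Box 4": 1.0, "AuxRR-core": 0.75, "P-box": 0.5,
                 "GARE-motif": 0.25, "LTR": 0.6, "W box": 0.0}
    records, truths, inc = synth_promoter_set(20, 600, sub, incidence, rng, catalog=sub)
    hits = scan_promoters(records, sub)
    profile = presence_frequency(hits, sub).set_index("element")
    for element in sub:
        assert profile.loc[element.name, "promoters_with_hit"] == len(inc[element.name])
    # exact coordinates and strand of every plant
    for rec, truth in zip(records, truths):
        found = {(h.element, h.start, h.end, h.strand) for h in hits[rec.gene_id]}
        for f in truth.features:
            assert (f.name, f.start, f.end, f.strand) in found


def test_synth_promoter_plan_validation(rng):
    with pytest.raises(ValueError, match="overlap"):
        synth_promoter(100, [PlantingPlan("a", "CACGTG", 10),
                             PlantingPlan("b", "GGTCCAT", 12)], rng)
    with pytest.raises(ValueError, match="fit"):
        synth_promoter(10, [PlantingPlan("a", "CACGTG", 8)], rng)
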