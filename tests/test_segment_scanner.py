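import numpy as np
import pytest

from dehydrinscan.segment_scanner import (
    AA,
    AA_INDEX,
    MatchSource,
    ScanParams,
    SegmentClass,
    SegmentMatch,
    SerinePattern,
    default_pattern,
    default_pspm,
    resolve_overlaps,
    scan_all_segments,
    scan_segment,
    write_pspm,
)
from dehydrinscan.synthetic_data import synth_dehydrin


class TestDefaultPattern:
    def test_k_pattern_layout(self):
        pat = default_pattern(SegmentClass.K)
        assert pat.width == 15
        assert pat.positions[6] == frozenset("DE")
        assert pat.positions[10] == frozenset("DE")
        assert pat.positions[8] == frozenset("IV")  # Ile with Val alternative
        assert pat.core == frozenset({3, 7, 8, 9, 13, 14})

    def test_y_pattern_layout(self):
        pat = default_pattern(SegmentClass.Y)
        assert pat.width == 7
        assert pat.positions[0] == frozenset("D")
        assert [pat.positions[i] for i in (3, 4, 5)] == [
            frozenset("G"), frozenset("N"), frozenset("P")
        ]

    def test_f_pattern_has_phe_dyad(self):
        pat = default_pattern(SegmentClass.F)
        assert pat.width == 12
        assert pat.positions[7] == frozenset("F")
        assert pat.positions[9] == frozenset("F")

    def test_s_pattern_structure(self):
        pat = default_pattern(SegmentClass.S)
        assert isinstance(pat, SerinePattern)
        assert pat.anchor[3] == frozenset("ST")
        assert (pat.tract_min, pat.tract_max) == (4, 8)


class TestDefaultPspm:
    @pytest.mark.parametrize("cls", list(SegmentClass))
    def test_columns_normalized_and_positive(self, cls):
        pspm = default_pspm(cls)
        assert np.allclose(pspm.probs.sum(axis=1), 1.0, atol=1e-9)
        assert (pspm.probs > 0).all()

    @pytest.mark.parametrize(
        "cls,pos,res,freq",
        [
            (SegmentClass.K, 1, "K", 0.81),
            (SegmentClass.K, 7, "K", 0.90),
            (SegmentClass.K, 9, "K", 0.90),
            (SegmentClass.K, 11, "K", 0.86),
            (SegmentClass.K, 13, "P", 0.84),
            (SegmentClass.K, 8, "V", 0.12),
            (SegmentClass.Y, 0, "D", 0.96),
            (SegmentClass.Y, 1, "E", 0.65),
            (SegmentClass.Y, 2, "Y", 0.62),
            (SegmentClass.Y, 4, "N", 0.92),
            (SegmentClass.F, 5, "G", 0.97),
            (SegmentClass.F, 7, "F", 0.98),
            (SegmentClass.F, 9, "F", 0.81),
            (SegmentClass.S, 0, "L", 0.87),
            (SegmentClass.S, 1, "H", 0.81),
            (SegmentClass.S, 2, "R", 0.86),
            (SegmentClass.S, 3, "S", 0.80),
        ],
    )
    def test_quoted_logo_frequencies(self, cls, pos, res, freq):
        pspm = default_pspm(cls)
        assert pspm.probs[pos, AA_INDEX[res]] == pytest.approx(freq, abs=0.005)

    def test_meme_style_serialization(self):
        text = write_pspm(default_pspm(SegmentClass.K))
        assert "letter-probability matrix: alength= 20 w= 15" in text
        assert len(text.strip().splitlines()) == 17


class TestScanConsensus:
    def test_k_consensus_single_match(self):
        matches = scan_segment("EKKGIMDKIKEKLPG", SegmentClass.K)
        assert len(matches) == 1
        m = matches[0]
        assert (m.start, m.end) == (0, 15)
        assert m.matched_seq == "EKKGIMDKIKEKLPG"
        assert m.score > 0
        assert m.source is MatchSource.REGEX

    def test_y_consensus(self):
        matches = scan_segment("DEYGNPV", SegmentClass.Y)
        assert [(m.start, m.end) for m in matches] == [(0, 7)]

    def test_val_variant_of_k_core_accepted(self):
        matches = scan_segment("EKKGIMDKVKEKLPG", SegmentClass.K)
        assert len(matches) == 1

    def test_core_mismatch_rejected_regardless_of_budget(self):
        # break the obligatory Gly at position 3
        seq = "EKK" + "A" + "IMDKIKEKLPG"
        assert scan_segment(seq, SegmentClass.K, ScanParams(mismatch_budget=10)) == []

    def test_mismatch_budget_on_non_core(self):
        # positions 1 (K) and 11 (K) mutated: 2 mismatches, allowed at m=2
        seq = "ERKGIMDKIKERLPG"
        assert len(scan_segment(seq, SegmentClass.K)) == 1
        assert scan_segment(seq, SegmentClass.K, ScanParams(mismatch_budget=1)) == []

    def test_s_variable_tract(self):
        for tract in (4, 7, 8):
            seq = "GG" + "LHRSG" + "S" * tract + "DEED" + "GG"
            matches = scan_segment(seq, SegmentClass.S)
            assert [(m.start, m.end) for m in matches] == [(2, 2 + 9 + tract)]

    def test_s_overlong_tract_rejected(self):
        seq = "GG" + "LHRSG" + "S" * 9 + "DEED" + "GG"
        assert scan_segment(seq, SegmentClass.S) == []

    def test_matched_seq_is_slice_of_parent(self):
        rec, _ = synth_dehydrin("FSK2", 3)
        for m in scan_all_segments(rec.sequence):
            assert m.matched_seq == rec.sequence[m.start : m.end]


def test_false_positive_rate_on_random_windows(rng):
    """~10,000 uniform-random windows should essentially never match K."""
    n_windows = 0
    n_hits = 0
    for _ in range(54):
        seq = "".join(AA[i] for i in rng.integers(20, size=200))
        n_windows += 200 - 15 + 1
        n_hits += len(scan_segment(seq, SegmentClass.K))
    assert n_windows >= 10000
    assert n_hits / n_windows < 1e-3


class TestBruteForceOracle:
    """Direct set-membership window checking on short sequences."""

    @staticmethod
    def _brute_fixed(seq, pattern, budget):
        out = []
        w = pattern.width
        for start in range(len(seq) - w + 1):
            window = seq[start : start + w]
            if any(window[i] not in pattern.positions[i] for i in pattern.core):
                continue
            mm = sum(
                1
                for i in range(w)
                if i not in pattern.core and window[i] not in pattern.positions[i]
            )
            if mm <= budget:
                out.append((start, start + w))
        return out

    @staticmethod
    def _brute_serine(seq, pattern, budget):
        out = []
        for start in range(len(seq)):
            for tract in range(pattern.tract_min, pattern.tract_max + 1):
                end = start + 5 + tract + 4
                if end > len(seq):
                    continue
                window = seq[start:end]
                tract_seq = window[5 : 5 + tract]
                if tract_seq != "S" * tract:
                    continue
                # maximal run: no S directly before or after the tract
                if window[4] == "S" or window[5 + tract] == "S":
                    continue
                if start + 5 + tract < len(seq) and seq[start + 5 + tract] == "S":
                    continue
                mm = sum(1 for c, al in zip(window[:5], pattern.anchor) if c not in al)
                mm += sum(1 for c, al in zip(window[5 + tract :], pattern.tail) if c not in al)
                if mm <= budget:
                    out.append((start, end))
        return out

    @pytest.mark.parametrize("cls", list(SegmentClass))
    def test_equivalence_on_short_sequences(self, cls, rng):
        pattern = default_pattern(cls)
        fixtures = [
            "EKKGIMDKIKEKLPG",
            "DEYGNPV" + "LHRSG" + "S" * 5 + "DEED",
            "AAEKKDRGLFDFLGAA",
            "GG" + "LHRTG" + "S" * 8 + "SDEE" + "GG",
        ]
        # random short sequences enriched in pattern letters to exercise edges
        letters = "KGIDESPFLHRVNYT"
        for _ in range(40):
            fixtures.append(
                "".join(letters[i] for i in rng.integers(len(letters), size=60))
            )
        for seq in fixtures:
            got = [(m.start, m.end) for m in scan_segment(seq, cls)]
            if isinstance(pattern, SerinePattern):
                want = self._brute_serine(seq, pattern, 2)
            else:
                want = self._brute_fixed(seq, pattern, 2)
            assert got == want, f"{cls} disagreement on {seq}"


def test_flank_shift_invariance():
    rec, _ = synth_dehydrin("Y2SK3", 17)
    base = [(m.segment_class, m.start, m.end) for m in scan_all_segments(rec.sequence)]
    flank_l, flank_r = "W" * 11, "W" * 6
    shifted = scan_all_segments(flank_l + rec.sequence + flank_r)
    got = [(m.segment_class, m.start - len(flank_l), m.end - len(flank_l)) for m in shifted]
    assert got == base


class TestResolveOverlaps:
    def _m(self, cls, start, end, score):
        return SegmentMatch(cls, start, end, "X" * (end - start), score)

    def test_tie_break_smaller_start(self):
        a = self._m(SegmentClass.K, 0, 15, 10.0)
        b = self._m(SegmentClass.K, 5, 20, 10.0)
        assert resolve_overlaps([b, a]) == [a]

    def test_disjoint_kept(self):
        a = self._m(SegmentClass.K, 0, 15, 10.0)
        b = self._m(SegmentClass.S, 30, 43, 5.0)
        assert resolve_overlaps([b, a]) == [a, b]

    def test_higher_score_wins_across_classes(self):
        k = self._m(SegmentClass.K, 0, 15, 10.0)
        f = self._m(SegmentClass.F, 10, 22, 20.0)
        assert resolve_overlaps([k, f]) == [f]


def test_planted_recovery_small_cohort():
    """Noise-free synthetic dehydrins are recovered with exact coordinates."""
    formulas = ["K", "K3", "SK2", "K2S", "Y2K2", "Y2SK3", "FSK4", "F2K2"]
    ok = total = 0
    for seed, formula in enumerate(formulas * 10):
        rec, truth = synth_dehydrin(formula, seed)
        found = [
            (m.segment_class.value, m.start, m.end)
            for m in scan_all_segments(rec.sequence)
        ]
        want = [(f.name, f.start, f.end) for f in truth.features]
        ok += found == want
        total += 1
    assert ok == total
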