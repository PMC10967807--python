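"""Locate the conserved K, Y, S and F segments of dehydrins.

Dehydrins are modular: a lysine-rich amphipathic K segment (obligatory),
an N-terminal Y segment, a phosphorylatable serine-tract S segment and a
phenylalanine-dyad F segment, separated by disordered Φ linkers. The scanner
finds these segments with degenerate consensus patterns and scores each hit
with a position-specific probability matrix (PSPM) seeded from published
per-position residue frequencies.

Patterns (0-based; {..} = allowed set, X = any residue):

    K  (width 15)  X K X G X X {DE} K {IV} K {DE} K X P G
                   core: 3-G, 7-K, 8-{I,V}, 9-K, 13-P, 14-G
    Y  (width 7)   D {DE} {YHF} G N P X          core: 0-D, 3-G, 4-N, 5-P
    S  (variable)  L H R {ST} G + S{4,8} + {SDE} {DE} {DE} {DE}
                   core: the serine tract (exact run of 4-8 Ser)
    F  (width 12)  E X X D R G X F D F X {GK}    core: 7-F, 9-F

A window is a match when every core position matches exactly and at most
``mismatch_budget`` non-core positions fall outside their allowed sets; it is
then scored as the PSPM log-odds (bits) against a uniform 1/20 background and
kept if the score reaches ``score_threshold``.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
_ANY = frozenset(AA)
N_AA = 20
UNIFORM_BG = 1.0 / N_AA


class SegmentClass(Enum):
    K = "K"
    Y = "Y"
    S = "S"
    F = "F"


class MatchSource(Enum):
    REGEX = "REGEX"
    PSPM = "PSPM"


@dataclass(frozen=True)
class SegmentMatch:
    """One located segment: class, coordinates, matched slice, PSPM score."""

    segment_class: SegmentClass
    start: int
    end: int
    matched_seq: str
    score: float
    source: MatchSource = MatchSource.REGEX


@dataclass(frozen=True)
class ScanParams:
    """Tunable scan parameters.

    mismatch_budget: substitutions tolerated at non-core pattern positions.
    score_threshold: minimum PSPM log-odds (bits) versus uniform background.
    pspm_only: ignore the degenerate pattern and accept any window whose
        score clears the threshold (fixed-width classes only).
    """

    mismatch_budget: int = 2
    score_threshold: float = 0.0
    pspm_only: bool = False


@dataclass(frozen=True)
class FixedPattern:
    """Fixed-width degenerate pattern: per-position allowed sets + core."""

    segment_class: SegmentClass
    positions: tuple[frozenset, ...]
    core: frozenset

    @property
    def width(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SerinePattern:
    """The variable-width S-segment pattern: anchor + Ser tract + acidic tail."""

    segment_class: SegmentClass
    anchor: tuple[frozenset, ...]
    tail: tuple[frozenset, ...]
    tract_min: int = 4
    tract_max: int = 8


def _sets(*specs: str) -> tuple[frozenset, ...]:
    return tuple(_ANY if s == "." else frozenset(s) for s in specs)


_K_PATTERN = FixedPattern(
    SegmentClass.K,
    _sets(".", "K", ".", "G", ".", ".", "DE", "K", "IV", "K", "DE", "K", ".", "P", "G"),
    frozenset({3, 7, 8, 9, 13, 14}),
)
_Y_PATTERN = FixedPattern(
    SegmentClass.Y,
    _sets("D", "DE", "YHF", "G", "N", "P", "."),
    frozenset({0, 3, 4, 5}),
)
_F_PATTERN = FixedPattern(
    SegmentClass.F,
    _sets("E", ".", ".", "D", "R", "G", ".", "F", "D", "F", ".", "GK"),
    frozenset({7, 9}),
)
_S_PATTERN = SerinePattern(
    SegmentClass.S,
    anchor=_sets("L", "H", "R", "ST", "G"),
    tail=_sets("SDE", "DE", "DE", "DE"),
)

_PATTERNS = {
    SegmentClass.K: _K_PATTERN,
    SegmentClass.Y: _Y_PATTERN,
    SegmentClass.S: _S_PATTERN,
    SegmentClass.F: _F_PATTERN,
}

# Reference widths per class (S uses the 7-Ser modal tract: 5 + 7 + 4 = 16)
WIDTHS = {SegmentClass.K: 15, SegmentClass.Y: 7, SegmentClass.F: 12}
S_REFERENCE_WIDTH = 16


def default_pattern(segment_class: SegmentClass) -> FixedPattern | SerinePattern:
    """The class's degenerate consensus pattern with per-position allowed sets."""
    try:
        return _PATTERNS[segment_class]
    except KeyError:
        raise ValueError(f"unknown segment class {segment_class!r}") from None


# ---------------------------------------------------------------------------
# Position-specific probability matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSPM:
    """Per-position residue probabilities for one segment class.

    ``probs`` has shape (width, 20), columns in the order ``AA``; every row
    sums to 1 and no entry is exactly zero (pseudocount floor).
    """

    segment_class: SegmentClass
    probs: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2(p / uniform background) per position and residue."""
        return np.log2(self.probs / UNIFORM_BG)


def _build_column(allowed: frozenset, quoted: dict[str, float], pseudocount: float) -> np.ndarray:
    col = np.zeros(N_AA)
    for res, p in quoted.items():
        col[AA_INDEX[res]] = p
    remaining = 1.0 - sum(quoted.values())
    unquoted_allowed = [r for r in allowed if r not in quoted]
    if unquoted_allowed:
        for r in unquoted_allowed:
            col[AA_INDEX[r]] = remaining / len(unquoted_allowed)
    elif remaining > 1e-12:
        # spread leftover mass over the residues not quoted at this position
        others = [r for r in AA if r not in quoted]
        for r in others:
            col[AA_INDEX[r]] += remaining / len(others)
    col += pseudocount
    return col / col.sum()


# Quoted per-position frequencies from the motif LOGOs (0-based positions).
_QUOTED = {
    SegmentClass.K: {
        1: {"K": 0.81},
        2: {"K": 0.81},
        3: {"G": 0.91},
        7: {"K": 0.90},
        8: {"V": 0.12},  # Ile dominant, Val the scored alternative
        9: {"K": 0.90},
        11: {"K": 0.86},
        13: {"P": 0.84},
        14: {"G": 0.91},
    },
    SegmentClass.Y: {
        0: {"D": 0.96},
        1: {"E": 0.65},
        2: {"Y": 0.62},
        3: {"G": 0.91},
        4: {"N": 0.92},
    },
    SegmentClass.F: {
        0: {"E": 0.94},
        4: {"R": 0.92},
        5: {"G": 0.97},
        # hydrophobic core weighting (Leu-Phe-Asp-Phe-Leu)
        6: {"L": 0.30},
        7: {"F": 0.98},
        9: {"F": 0.81},
        10: {"L": 0.30},
        11: {"K": 0.97},
    },
}

# S-segment quoted anchor frequencies; tract and tail handled structurally.
_S_QUOTED = {0: {"L": 0.87}, 1: {"H": 0.81}, 2: {"R": 0.86}, 3: {"S": 0.80}}


def default_pspm(segment_class: SegmentClass, pseudocount: float = 1e-4) -> PSPM:
    """PSPM seeded from the published LOGO frequencies.

    Quoted frequencies go to their residues; the rest of each column's mass is
    spread uniformly over the residues the degenerate pattern allows, then a
    pseudocount floor guarantees no zero probability. The S matrix uses the
    modal 16-column layout (anchor 5 + seven-Ser tract + tail 4); variable-
    width S matches are scored against it by mapping tract residues onto the
    tract columns.
    """
    pattern = default_pattern(segment_class)
    if isinstance(pattern, SerinePattern):
        cols = []
        for i, allowed in enumerate(pattern.anchor):
            cols.append(_build_column(allowed, _S_QUOTED.get(i, {}), pseudocount))
        for _ in range(7):
            cols.append(_build_column(frozenset("S"), {}, pseudocount))
        for allowed in pattern.tail:
            cols.append(_build_column(allowed, {}, pseudocount))
        return PSPM(segment_class, np.array(cols), pseudocount)
    quoted = _QUOTED[segment_class]
    cols = [
        _build_column(allowed, quoted.get(i, {}), pseudocount)
        for i, allowed in enumerate(pattern.positions)
    ]
    return PSPM(segment_class, np.array(cols), pseudocount)


def write_pspm(pspm: PSPM) -> str:
    """Serialize a PSPM as a MEME-minimal-style letter-probability block."""
    lines = [
        f"MOTIF {pspm.segment_class.value}-segment",
        f"letter-probability matrix: alength= {N_AA} w= {pspm.width}",
    ]
    for row in pspm.probs:
        lines.append(" ".join(f"{p:.6f}" for p in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _encode(sequence: str) -> np.ndarray:
    """Residues to integer codes; X (or any unknown) becomes code 20."""
    codes = np.full(len(sequence), N_AA, dtype=np.int64)
    for i, ch in enumerate(sequence):
        codes[i] = AA_INDEX.get(ch, N_AA)
    return codes


def _allowed_mask(pattern: FixedPattern) -> np.ndarray:
    """(width, 21) boolean: does residue code match position? X matches only 'any'."""
    mask = np.zeros((pattern.width, N_AA + 1), dtype=bool)
    for i, allowed in enumerate(pattern.positions):
        for r in allowed:
            mask[i, AA_INDEX[r]] = True
        if allowed == _ANY:
            mask[i, N_AA] = True
    return mask


def _score_table(pspm: PSPM) -> np.ndarray:
    """(width, 21) log-odds lookup; X residues contribute 0 bits."""
    table = np.zeros((pspm.width, N_AA + 1))
    table[:, :N_AA] = pspm.log_odds()
    return table


def _mismatch_count(seq_chars: Sequence[str], sets: Sequence[frozenset]) -> int:
    return sum(1 for ch, allowed in zip(seq_chars, sets) if ch not in allowed)


def _scan_fixed(sequence: str, pattern: FixedPattern, pspm: PSPM, params: ScanParams) -> list[SegmentMatch]:
    w = pattern.width
    n = len(sequence)
    if n < w:
        return []
    codes = _encode(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    table = _score_table(pspm)
    scores = table[np.arange(w), windows].sum(axis=1)
    if params.pspm_only:
        keep = scores >= params.score_threshold
    else:
        mask = _allowed_mask(pattern)
        ok = mask[np.arange(w), windows]  # (n-w+1, w)
        core = np.fromiter((i in pattern.core for i in range(w)), dtype=bool, count=w)
        core_ok = ok[:, core].all(axis=1)
        mismatches = (~ok[:, ~core]).sum(axis=1)
        keep = core_ok & (mismatches <= params.mismatch_budget) & (scores >= params.score_threshold)
    out = []
    source = MatchSource.PSPM if params.pspm_only else MatchSource.REGEX
    for start in np.nonzero(keep)[0]:
        start = int(start)
        out.append(
            SegmentMatch(
                pattern.segment_class, start, start + w,
                sequence[start : start + w], float(scores[start]), source,
            )
        )
    return out


_S_RUN = re.compile("S{4,}")


def _score_s_match(window: str, tract_len: int, pspm: PSPM) -> float:
    table = pspm.log_odds()
    score = 0.0
    for j in range(5):  # anchor
        code = AA_INDEX.get(window[j])
        score += table[j, code] if code is not None else 0.0
    for j in range(tract_len):  # tract residues map onto columns 5..11
        col = 5 + min(j, 6)
        code = AA_INDEX.get(window[5 + j])
        score += table[col, code] if code is not None else 0.0
    for j in range(4):  # tail -> columns 12..15
        code = AA_INDEX.get(window[5 + tract_len + j])
        score += table[12 + j, code] if code is not None else 0.0
    return score


def _scan_serine(sequence: str, pattern: SerinePattern, pspm: PSPM, params: ScanParams) -> list[SegmentMatch]:
    out = []
    for run in _S_RUN.finditer(sequence):
        tract_len = run.end() - run.start()
        if tract_len > pattern.tract_max:
            continue  # longer runs fall outside the segment definition
        start = run.start() - len(pattern.anchor)
        end = run.end() + len(pattern.tail)
        if start < 0 or end > len(sequence):
            continue
        anchor_mm = _mismatch_count(sequence[start : run.start()], pattern.anchor)
        tail_mm = _mismatch_count(sequence[run.end() : end], pattern.tail)
        if anchor_mm + tail_mm > params.mismatch_budget:
            continue
        window = sequence[start:end]
        score = _score_s_match(window, tract_len, pspm)
        if score >= params.score_threshold:
            out.append(SegmentMatch(SegmentClass.S, start, end, window, score))
    return out


def scan_segment(
    sequence: str,
    segment_class: SegmentClass,
    params: ScanParams | None = None,
    pspm: PSPM | None = None,
) -> list[SegmentMatch]:
    """All matches of one segment class in a sequence, sorted by start."""
    params = params or ScanParams()
    pattern = default_pattern(segment_class)
    pspm = pspm or default_pspm(segment_class)
    sequence = sequence.upper()
    if isinstance(pattern, SerinePattern):
        matches = _scan_serine(sequence, pattern, pspm, params)
    else:
        matches = _scan_fixed(sequence, pattern, pspm, params)
    return sorted(matches, key=lambda m: m.start)


def scan_all_segments(sequence: str, params: ScanParams | None = None) -> list[SegmentMatch]:
    """Scan all four classes and resolve overlaps; sorted by start."""
    matches: list[SegmentMatch] = []
    for cls in SegmentClass:
        matches.extend(scan_segment(sequence, cls, params))
    return resolve_overlaps(matches)


def resolve_overlaps(matches: Iterable[SegmentMatch]) -> list[SegmentMatch]:
    """Greedy non-overlap selection: best score first, ties to smaller start.

    One residue belongs to one segment, so overlap is forbidden across
    classes as well as within a class.
    """
    chosen: list[SegmentMatch] = []
    for cand in sorted(matches, key=lambda m: (-m.score, m.start)):
        if all(cand.end <= kept.start or cand.start >= kept.end for kept in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda m: m.start)
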