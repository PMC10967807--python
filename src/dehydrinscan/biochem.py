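"""Per-sequence biochemical properties of dehydrins.

Computes the quantities usually obtained from ProtParam and FoldIndex:
average molecular weight, isoelectric point (Bjellqvist pKa set,
Henderson–Hasselbalch charge model solved by bisection), GRAVY
(mean Kyte–Doolittle hydropathy), the fold index

    FI = 2.785 * <H> - |<R>| - 1.151

with <H> the mean hydrophobicity rescaled to [0, 1] as (KD + 4.5)/9 and <R>
the mean net charge (K, R = +1; D, E = -1; His neutral), and residue
percentages. Negative GRAVY marks a hydrophilic protein; negative fold index
predicts intrinsic disorder.

X residues are retained in sequences but excluded from every average and
sum here: no physical constants exist for an unknown residue.

Constants ship as two plain-text tables (``data/masses_hydropathy.tsv``,
``data/pka_bjellqvist.tsv``) loaded at import; an alternative pKa set (e.g.
EMBOSS) can be supplied per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

WATER_MASS = 18.0153
_DATA = resources.files("dehydrinscan") / "data"


def _read_table(name: str) -> list[list[str]]:
    rows = []
    for line in (_DATA / name).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


def load_constant_tables() -> tuple[dict[str, float], dict[str, float]]:
    """Load (average residue masses, Kyte–Doolittle hydropathy) tables."""
    masses, kd = {}, {}
    for res, mass, hydro in _read_table("masses_hydropathy.tsv"):
        masses[res] = float(mass)
        kd[res] = float(hydro)
    if len(masses) != 20 or len(kd) != 20:
        raise ValueError("constants table must define exactly 20 residues")
    return masses, kd


def load_pka_table(path: str | Path | None = None) -> dict[str, tuple[float, int]]:
    """Load the pKa table: site -> (pKa, charge sign).

    Sites are the N- and C-terminus plus the ionizable side chains
    D, E, C, Y (acidic) and K, R, H (basic). ``path`` overrides the shipped
    Bjellqvist set.
    """
    if path is None:
        rows = _read_table("pka_bjellqvist.tsv")
    else:
        rows = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                rows.append(line.split("\t"))
    table = {site: (float(pka), int(sign)) for site, pka, sign in rows}
    for required in ("NTERM", "CTERM"):
        if required not in table:
            raise ValueError(f"pKa table missing {required}")
    return table


MASSES, KD = load_constant_tables()
PKA_BJELLQVIST = load_pka_table()

# net-charge contributions for the fold index (His neutral, FoldIndex convention)
_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


@dataclass(frozen=True)
class BiochemProfile:
    """The six headline properties of one sequence plus its length."""

    mw: float
    pi: float
    gravy: float
    fold_index: float
    lys_pct: float
    his_pct: float
    length: int


def _effective(sequence: str) -> str:
    """Residues entering averages: everything but X."""
    seq = sequence.upper()
    bad = set(seq) - set(MASSES) - {"X"}
    if bad:
        raise ValueError(f"unknown residue letters {sorted(bad)}")
    eff = seq.replace("X", "")
    if not eff:
        raise ValueError("sequence has no non-X residues")
    return eff


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in daltons (residue masses + one water)."""
    eff = _effective(sequence)
    return sum(MASSES[r] for r in eff) + WATER_MASS


def net_charge(sequence: str, ph: float, pka: dict[str, tuple[float, int]] | None = None) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Basic sites contribute 1/(1+10^(pH-pKa)), acidic sites -1/(1+10^(pKa-pH));
    both termini always count, X side chains never do.
    """
    table = PKA_BJELLQVIST if pka is None else pka
    eff = _effective(sequence)
    charge = 0.0
    sites = [("NTERM", 1), ("CTERM", 1)]
    sites += [(r, eff.count(r)) for r in set(eff) if r in table]
    for site, count in sites:
        pk, sign = table[site]
        if sign > 0:
            charge += count / (1.0 + 10.0 ** (ph - pk))
        else:
            charge -= count / (1.0 + 10.0 ** (pk - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka: dict[str, tuple[float, int]] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge curve is strictly decreasing in pH, so the zero crossing is
    unique; bisection stops when |charge| < ``tol``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle over non-X residues."""
    eff = _effective(sequence)
    return sum(KD[r] for r in eff) / len(eff)


def fold_index(sequence: str) -> float:
    """Whole-sequence fold index; negative values predict disorder."""
    eff = _effective(sequence)
    mean_h = sum((KD[r] + 4.5) / 9.0 for r in eff) / len(eff)
    mean_r = sum(_CHARGE.get(r, 0.0) for r in eff) / len(eff)
    return 2.785 * mean_h - abs(mean_r) - 1.151


def fold_index_profile(sequence: str, window: int = 51) -> np.ndarray:
    """Sliding-window fold index (the FoldIndex per-residue profile).

    Windows shorter than ``window`` at the ends are averaged over what is
    available; X residues are skipped inside each window.
    """
    seq = sequence.upper()
    n = len(seq)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        chunk = seq[max(0, i - half) : min(n, i + half + 1)].replace("X", "")
        if not chunk:
            out[i] = np.nan
            continue
        mean_h = sum((KD[r] + 4.5) / 9.0 for r in chunk) / len(chunk)
        mean_r = sum(_CHARGE.get(r, 0.0) for r in chunk) / len(chunk)
        out[i] = 2.785 * mean_h - abs(mean_r) - 1.151
    return out


def residue_percent(sequence: str, residue: str) -> float:
    """Percentage of one residue over non-X positions."""
    if len(residue) != 1:
        raise ValueError("residue must be a single letter")
    eff = _effective(sequence)
    return 100.0 * eff.count(residue.upper()) / len(eff)


def biochem_profile(sequence: str) -> BiochemProfile:
    """Compute all headline properties for one sequence."""
    eff = _effective(sequence)
    return BiochemProfile(
        mw=molecular_weight(sequence),
        pi=isoelectric_point(sequence),
        gravy=gravy(sequence),
        fold_index=fold_index(sequence),
        lys_pct=100.0 * eff.count("K") / len(eff),
        his_pct=100.0 * eff.count("H") / len(eff),
        length=len(sequence),
    )
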