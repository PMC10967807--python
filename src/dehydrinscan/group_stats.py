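"""Group summaries and the Games–Howell pairwise comparison.

The Games–Howell procedure compares every pair of groups without assuming
equal variances or equal sample sizes: each pair gets a Welch standard error
SE = sqrt(s_i^2/n_i + s_j^2/n_j), Welch–Satterthwaite degrees of freedom, a
studentized-range statistic q = |mean_i - mean_j| / sqrt(SE^2 / 2), and a
p-value from the studentized range distribution with k (the total number of
groups) and those df — giving familywise control across the pairs.

The studentized-range CDF comes from scipy's exact double-integral
quadrature (``scipy.stats.studentized_range``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Five-number summary of one variable within one group."""

    group: str
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


@dataclass(frozen=True)
class PairwiseResult:
    """One Games–Howell pairwise comparison."""

    group_a: str
    group_b: str
    mean_diff: float
    se: float
    welch_df: float
    q_statistic: float
    p_value: float
    significant: bool


def summarize_groups(values_by_group: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Five-number summaries (quartiles by linear interpolation)."""
    out = []
    for group in values_by_group:
        x = np.asarray(values_by_group[group], dtype=float)
        if x.size == 0:
            raise ValueError(f"group {group!r} is empty")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        out.append(
            GroupSummary(group, int(x.size), float(x.min()), float(q1), float(med), float(q3), float(x.max()))
        )
    return out


def games_howell(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> list[PairwiseResult]:
    """Games–Howell pairwise tests over all group pairs.

    Every group needs n >= 2 and nonzero variance. ``significant`` is
    p < alpha. Results are one entry per unordered pair, in the order the
    groups appear in the mapping.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for g in names:
        x = np.asarray(values_by_group[g], dtype=float)
        if x.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
        if np.var(x, ddof=1) == 0:
            raise ValueError(f"group {g!r} has zero variance")
        arrays[g] = x
    k = len(names)
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[names[i]], arrays[names[j]]
            va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
            se = float(np.sqrt(va + vb))
            diff = float(a.mean() - b.mean())
            df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
            q = abs(diff) / np.sqrt((va + vb) / 2.0)
            p = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
            results.append(
                PairwiseResult(
                    names[i], names[j], diff, se, float(df), float(q), p, bool(p < alpha)
                )
            )
    return results
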