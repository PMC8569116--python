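"""Shared statistical tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RankSumResult", "wilcoxon_rank_sum_one_sided"]


@dataclass
class RankSumResult:
    pvalue: float
    statistic: float
    method: str  # "exact" | "asymptotic"
    alternative: str


def wilcoxon_rank_sum_one_sided(x, y, alternative: str = "less") -> RankSumResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``alternative='less'`` tests that ``x`` is stochastically smaller than
    ``y``; ``'greater'`` the opposite.  For small tie-free samples
    (n_x + n_y <= 12) the p-value is exact (full enumeration of the U null
    distribution); otherwise a normal approximation with tie and continuity
    corrections is used.  The method actually applied is recorded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return RankSumResult(float(res.pvalue), float(res.statistic), method, alternative)
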