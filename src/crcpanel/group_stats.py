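"""Non-parametric and categorical group comparisons.

These are the descriptive-table tests of a case-control marker study:
Wilcoxon rank-sum for a skewed marker between two groups, Kruskal-Wallis
across T stages, and Pearson's chi-square for FOBT positivity.  All
p-values are two-sided; ties are handled with midranks and the usual
tie-corrected large-sample approximations (the small-sample exact null
is left to permutation oracles in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["TestResult", "wilcoxon_rank_sum", "kruskal_wallis", "pearson_chi_square"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    The reported statistic is the rank-sum of ``x`` in the pooled
    midranked sample; the p-value uses the tie-corrected normal
    approximation without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=False)
    # U of x relates to its rank-sum W by W = U + n1(n1+1)/2
    w = float(u) + x.size * (x.size + 1) / 2.0
    return TestResult(statistic=w, p_value=float(p),
                      method="wilcoxon-rank-sum", n=(x.size, y.size))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if np.ptp(np.concatenate(arrays)) == 0:
        # scipy raises on all-identical data; H is identically 0 there
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal-wallis",
                          n=tuple(a.size for a in arrays))
    h, p = stats.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p),
                      method="kruskal-wallis", n=tuple(a.size for a in arrays))


def pearson_chi_square(table: Sequence[Sequence[int]],
                       continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table.

    Uncorrected by default; Yates continuity correction is available for
    2x2 tables via ``continuity_correction=True``.
    """
    counts = np.asarray(table)
    if counts.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column margin")
    res = stats.chi2_contingency(counts, correction=continuity_correction)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="pearson-chi-square",
                      n=tuple(int(m) for m in counts.sum(axis=1)))
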