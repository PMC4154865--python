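"""Empirical ROC analysis: AUC, high-specificity partial AUC, operating
points, and the DeLong paired test for the increase in AUC.

A subject is called positive when its score is at or above the
threshold.  AUC is the trapezoidal area, which for an empirical curve
equals the Mann-Whitney probability that a random case outscores a
random control with ties counted one half.  The partial AUC restricts
the area to a specificity window (by default 90-100%, so a perfect
classifier attains 0.10) and is reported unnormalized; McClish
standardization to [0.5, 1] is available by flag.

The paired AUC comparison follows DeLong's structural-component
(placement-value) estimator of the covariance between the two
correlated AUCs, with a two-sided normal test on the difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCCurve",
    "DeLongResult",
    "empirical_roc",
    "auc",
    "partial_auc",
    "sensitivity_at_spec_closest",
    "delong_test",
    "placement_values",
]


def _as_case_indicator(labels: Sequence) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "USO":
        ind = np.asarray([l == "case" for l in lab], dtype=bool)
    else:
        ind = lab.astype(bool)
    return ind


@dataclass(frozen=True)
class ROCCurve:
    """Operating points (threshold, sensitivity, specificity).

    Points are stored in order of increasing specificity (decreasing
    threshold leniency) and always include the trivial endpoints
    (sens 1, spec 0) and (sens 0, spec 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        for name in ("thresholds", "sensitivity", "specificity"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.thresholds.size == self.sensitivity.size
                == self.specificity.size):
            raise ValueError("point arrays must have equal length")
        sens, spec = self.sensitivity, self.specificity
        if np.any((sens < 0) | (sens > 1)) or np.any((spec < 0) | (spec > 1)):
            raise ValueError("sensitivity/specificity must lie in [0, 1]")
        if np.any(np.diff(spec) < 0) or np.any(np.diff(sens) > 0):
            raise ValueError("curve must be monotone in specificity")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def empirical_roc(scores: Sequence[float], labels: Sequence) -> ROCCurve:
    """ROC curve with one operating point per distinct score.

    ``labels`` may be "case"/"control" strings or a boolean/0-1 case
    indicator; higher scores must be more case-like.
    """
    scores = np.asarray(scores, dtype=float)
    is_case = _as_case_indicator(labels)
    if scores.size != is_case.size:
        raise ValueError("scores and labels must have equal length")
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    case_scores = scores[is_case]
    ctrl_scores = scores[~is_case]
    thresholds = np.unique(scores)[::-1]  # descending
    sens = np.array([(case_scores >= t).mean() for t in thresholds])
    spec = np.array([(ctrl_scores < t).mean() for t in thresholds])
    thresholds = np.concatenate([[-np.inf], thresholds[::-1], [np.inf]])
    sens = np.concatenate([[1.0], sens[::-1], [0.0]])
    spec = np.concatenate([[0.0], spec[::-1], [1.0]])
    # drop consecutive duplicate points (identical sens and spec)
    keep = np.ones(sens.size, dtype=bool)
    keep[1:] = (np.diff(sens) != 0) | (np.diff(spec) != 0)
    return ROCCurve(thresholds=thresholds[keep], sensitivity=sens[keep],
                    specificity=spec[keep], n_case=n1, n_control=n0)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area; equals the tie-adjusted Mann-Whitney statistic."""
    spec, sens = curve.specificity, curve.sensitivity
    return float(np.sum(np.diff(spec) * (sens[1:] + sens[:-1]) / 2.0))


def partial_auc(curve: ROCCurve, spec_range: tuple[float, float] = (0.90, 1.0),
                standardized: bool = False) -> float:
    """Area of sensitivity over a specificity window.

    Unnormalized by default: the maximum is the window width (0.10 for
    the 90-100% window).  ``standardized=True`` applies the McClish
    transformation onto [0.5, 1] relative to the chance area in the
    same window.  Segment ends are linearly interpolated at the window
    boundaries.
    """
    lo, hi = spec_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("need 0 <= lo < hi <= 1")
    spec, sens = curve.specificity, curve.sensitivity
    area = 0.0
    for i in range(spec.size - 1):
        s0, s1 = spec[i], spec[i + 1]
        if s1 <= lo or s0 >= hi or s1 == s0:
            continue
        a, b = max(s0, lo), min(s1, hi)
        ya = sens[i] + (sens[i + 1] - sens[i]) * (a - s0) / (s1 - s0)
        yb = sens[i] + (sens[i + 1] - sens[i]) * (b - s0) / (s1 - s0)
        area += (b - a) * (ya + yb) / 2.0
    if not standardized:
        return float(area)
    width = hi - lo
    chance = (2.0 - lo - hi) * width / 2.0  # area of the diagonal segment
    return float(0.5 * (1.0 + (area - chance) / (width - chance)))


def sensitivity_at_spec_closest(curve: ROCCurve, target: float = 0.90
                                ) -> tuple[float, float, float]:
    """Operating point whose achieved specificity is closest to target.

    Returns ``(sensitivity, achieved_specificity, threshold)``.  When
    two achievable points are equidistant from the target the higher
    specificity wins (the conservative choice for a screening test).
    """
    if not (0.0 <= target <= 1.0):
        raise ValueError("target specificity must lie in [0, 1]")
    spec = curve.specificity
    dist = np.abs(spec - target)
    best = np.flatnonzero(dist == dist.min())
    idx = best[np.argmax(spec[best])]
    return (float(curve.sensitivity[idx]), float(spec[idx]),
            float(curve.thresholds[idx]))


def placement_values(scores: Sequence[float], labels: Sequence
                     ) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components.

    For case i, ``V10[i]`` is the fraction of controls it beats (ties
    half); ``V01[j]`` symmetrically for control j.  Both average to the
    AUC.  Computed with midranks in O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    is_case = _as_case_indicator(labels)
    x, y = scores[is_case], scores[~is_case]
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("need at least one case and one control")
    all_ranks = stats.rankdata(np.concatenate([x, y]), method="average")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    v10 = (all_ranks[:m] - rx) / n
    v01 = 1.0 - (all_ranks[m:] - ry) / m
    return v10, v01


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two AUCs on the same subjects."""

    auc_1: float
    auc_2: float
    delta: float
    variance_delta: float
    z: float
    p_value: float
    ci_95_auc_1: tuple[float, float]
    ci_95_auc_2: tuple[float, float]
    degenerate: bool = False


def delong_test(scores_model1: Sequence[float],
                scores_model2: Sequence[float],
                labels: Sequence) -> DeLongResult:
    """DeLong test of the AUC increase from model 1 to model 2.

    Both score vectors must be computed on the same subjects in the
    same order.  If every placement difference is identical the
    variance of the AUC difference is zero and the test is undefined;
    this is reported via ``degenerate=True`` with NaN z and p.
    """
    s1 = np.asarray(scores_model1, dtype=float)
    s2 = np.asarray(scores_model2, dtype=float)
    if s1.size != s2.size:
        raise ValueError("score vectors must cover the same subjects")
    is_case = _as_case_indicator(labels)
    m, n = int(is_case.sum()), int((~is_case).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k, s in enumerate((s1, s2)):
        v10[k], v01[k] = placement_values(s, is_case)
    auc1, auc2 = v10.mean(axis=1)
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    var_delta = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    var_auc = np.array([s10[0, 0] / m + s01[0, 0] / n,
                        s10[1, 1] / m + s01[1, 1] / n])
    se_auc = np.sqrt(np.maximum(var_auc, 0.0))
    delta = float(auc2 - auc1)
    if var_delta <= 0:
        if delta == 0.0:
            z, p, degenerate = 0.0, 1.0, True
        else:
            z, p, degenerate = float("nan"), float("nan"), True
    else:
        z = delta / float(np.sqrt(var_delta))
        p = float(2.0 * stats.norm.sf(abs(z)))
        degenerate = False
    ci = [(float(a - 1.96 * se), float(a + 1.96 * se))
          for a, se in zip((auc1, auc2), se_auc)]
    return DeLongResult(
        auc_1=float(auc1), auc_2=float(auc2), delta=delta,
        variance_delta=float(max(var_delta, 0.0)), z=float(z),
        p_value=float(p), ci_95_auc_1=ci[0], ci_95_auc_2=ci[1],
        degenerate=degenerate,
    )
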