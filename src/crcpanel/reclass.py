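"""Category-free reclassification improvement (RI) and net
reclassification improvement (NRI).

For a nested pair of risk models, RI among cases is the proportion of
cases whose predicted probability rises under the richer model minus
the proportion whose probability falls; RI among controls is the
proportion falling minus the proportion rising.  Their sum is the NRI,
which ranges over [-2, 2].  Subjects whose probability is exactly
unchanged count in neither direction.  Significance uses the asymptotic
normal test with per-group variance (p_up + p_down - (p_up - p_down)^2)/n,
which is known to be somewhat anti-conservative in small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from crcpanel.roc import _as_case_indicator

__all__ = ["ReclassResult", "reclassification"]


@dataclass(frozen=True)
class ReclassResult:
    """Up/down movement proportions, RI per group, NRI, and tests."""

    p_up_case: float
    p_down_case: float
    p_up_ctrl: float
    p_down_ctrl: float
    ri_case: float
    ri_ctrl: float
    nri: float
    z_case: float
    z_ctrl: float
    z_nri: float
    p_case: float
    p_ctrl: float
    p_nri: float
    n_case: int
    n_control: int


def _group_movement(old: np.ndarray, new: np.ndarray) -> tuple[float, float]:
    up = float((new > old).mean())
    down = float((new < old).mean())
    return up, down


def _z_p(estimate: float, variance: float) -> tuple[float, float]:
    if variance <= 0:
        # no movement at all: the estimate is identically its value
        return (0.0, 1.0) if estimate == 0 else (float("inf"), 0.0)
    z = estimate / float(np.sqrt(variance))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def reclassification(p_old: Sequence[float], p_new: Sequence[float],
                     labels: Sequence) -> ReclassResult:
    """RI in cases and controls and their sum (NRI), with z-tests.

    ``p_old`` and ``p_new`` are predicted probabilities from the nested
    and the extended model for the same subjects in the same order.
    """
    old = np.asarray(p_old, dtype=float)
    new = np.asarray(p_new, dtype=float)
    if old.size != new.size:
        raise ValueError("probability vectors must have equal length")
    if np.any((old < 0) | (old > 1)) or np.any((new < 0) | (new > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    is_case = _as_case_indicator(labels)
    if is_case.size != old.size:
        raise ValueError("labels must match the probability vectors")
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")

    up1, down1 = _group_movement(old[is_case], new[is_case])
    up0, down0 = _group_movement(old[~is_case], new[~is_case])
    ri_case = up1 - down1
    ri_ctrl = down0 - up0
    nri = ri_case + ri_ctrl

    var_case = (up1 + down1 - (up1 - down1) ** 2) / n1
    var_ctrl = (up0 + down0 - (up0 - down0) ** 2) / n0
    z_case, p_case = _z_p(ri_case, var_case)
    z_ctrl, p_ctrl = _z_p(ri_ctrl, var_ctrl)
    z_nri, p_nri = _z_p(nri, var_case + var_ctrl)

    return ReclassResult(
        p_up_case=up1, p_down_case=down1, p_up_ctrl=up0, p_down_ctrl=down0,
        ri_case=ri_case, ri_ctrl=ri_ctrl, nri=nri,
        z_case=z_case, z_ctrl=z_ctrl, z_nri=z_nri,
        p_case=p_case, p_ctrl=p_ctrl, p_nri=p_nri,
        n_case=n1, n_control=n0,
    )
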