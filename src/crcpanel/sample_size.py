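"""Exact-binomial design calculations for diagnostic accuracy studies.

When planning a validation cohort one asks: if the true sensitivity (or
specificity) is ``true_value``, how likely is it that the exact
Clopper-Pearson lower confidence limit computed from the observed
successes will land above a floor ``lower_limit``?  That probability —
the *assurance* — is an exact finite sum over the binomial distribution
of the observed count, with no normal approximation anywhere.  The
module also inverts the calculation (smallest n achieving a target
assurance) and applies a ceiling-rule dropout inflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AssuranceSpec",
    "exact_lower_limit",
    "assurance_probability",
    "required_n",
    "inflate_for_dropout",
]


@dataclass(frozen=True)
class AssuranceSpec:
    """One assurance question: n subjects, true proportion, floor."""

    n: int
    true_value: float
    lower_limit: float
    confidence: float = 0.95
    sided: str = "one"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 < self.lower_limit < self.true_value < 1.0):
            raise ValueError("require 0 < lower_limit < true_value < 1")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must lie in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be one|two")


def exact_lower_limit(k: int, n: int, confidence: float = 0.95,
                      sided: str = "one") -> float:
    """Clopper-Pearson lower confidence bound for k successes in n trials.

    One-sided uses the full (1 - confidence) in the lower tail; the
    two-sided bound splits it.  ``k = 0`` gives 0 by convention.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("require 0 <= k <= n with n >= 1")
    if sided not in ("one", "two"):
        raise ValueError("sided must be one|two")
    if k == 0:
        return 0.0
    alpha = 1.0 - confidence
    if sided == "two":
        alpha /= 2.0
    return float(stats.beta.ppf(alpha, k, n - k + 1))


def _lower_limits(n: int, confidence: float, sided: str) -> np.ndarray:
    return np.array([exact_lower_limit(k, n, confidence, sided)
                     for k in range(n + 1)])


def assurance_probability(spec: AssuranceSpec) -> float:
    """P(exact lower confidence limit > floor) under Binomial(n, true).

    Computed by exact enumeration of k = 0..n; deterministic.
    """
    limits = _lower_limits(spec.n, spec.confidence, spec.sided)
    pmf = stats.binom.pmf(np.arange(spec.n + 1), spec.n, spec.true_value)
    return float(pmf[limits > spec.lower_limit].sum())


def required_n(true_value: float, lower_limit: float, assurance: float,
               confidence: float = 0.95, sided: str = "one",
               n_cap: int = 2000) -> int:
    """Smallest n whose assurance probability reaches the target.

    The assurance is not exactly monotone in n (exact-binomial
    saw-tooth), so the search scans upward and returns the first n that
    meets the target; raises if no n up to ``n_cap`` does.
    """
    if not (0.0 < assurance < 1.0):
        raise ValueError("assurance must lie in (0, 1)")
    for n in range(1, n_cap + 1):
        spec = AssuranceSpec(n=n, true_value=true_value,
                             lower_limit=lower_limit,
                             confidence=confidence, sided=sided)
        if assurance_probability(spec) >= assurance:
            return n
    raise ValueError(f"no n <= {n_cap} reaches assurance {assurance}")


def inflate_for_dropout(n: int, dropout_rate: float) -> int:
    """Smallest m with m*(1 - rate) >= n (ceiling rule)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must lie in [0, 1)")
    m = int(np.ceil(n / (1.0 - dropout_rate)))
    # guard against floating-point edge: enforce the defining inequality
    while m * (1.0 - dropout_rate) < n:
        m += 1
    while (m - 1) * (1.0 - dropout_rate) >= n and m > n:
        m -= 1
    return m
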