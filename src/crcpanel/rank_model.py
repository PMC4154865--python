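"""Rank-transform logistic modelling and the rank-lookup scoring equation.

The continuous marker (CALB optical density) is heavily non-normal —
zero-inflated and right-skewed — so it enters the logistic model as its
midrank within the fitting set rather than as the raw optical density.
Two nested, age-adjusted models are supported:

* model 1:  logit P(case) = b0 + b1*AGE + b2*FOBT
* model 2:  logit P(case) = b0 + b1*AGE + b2*FOBT + b3*R(CALB)

where R(CALB) is the midrank (1..n, midranks for ties) of the subject's
CALB value among the n subjects used for fitting.  To score a *future*
subject the fitted model carries its :class:`RankTable` — the sorted
distinct CALB values with their midranks — and R(CALB) is read off by
exact match, nearest entry, or linear interpolation, clamped to the
table's extremes for out-of-range values.  Because only ranks enter, the
fit and all predictions are invariant to any strictly increasing
transformation of the marker.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from crcpanel.synthetic import SubjectRecord

__all__ = [
    "RankTable",
    "LogisticModel",
    "midrank_transform",
    "build_rank_table",
    "rank_lookup",
    "fit_logistic",
    "predict_probability",
    "predict_probabilities",
]

MODEL1_TERMS = ("intercept", "age", "fobt")
MODEL2_TERMS = ("intercept", "age", "fobt", "rank_calb")


def midrank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with midranks for ties; rank sum is n(n+1)/2."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty list")
    return stats.rankdata(values, method="average")


@dataclass(frozen=True)
class RankTable:
    """Sorted distinct marker values with their midranks.

    This is the published-style lookup table that accompanies the final
    scoring equation: one row per distinct optical density observed in
    the fitting set, carrying the midrank that value received among all
    ``n`` fitted subjects.
    """

    calb_od: np.ndarray
    rank: np.ndarray
    n: int

    def __post_init__(self) -> None:
        od = np.asarray(self.calb_od, dtype=float)
        rk = np.asarray(self.rank, dtype=float)
        object.__setattr__(self, "calb_od", od)
        object.__setattr__(self, "rank", rk)
        if od.size == 0:
            raise ValueError("rank table must be non-empty")
        if od.size != rk.size:
            raise ValueError("calb_od and rank must have equal length")
        if np.any(np.diff(od) <= 0):
            raise ValueError("calb_od must be strictly increasing")
        if np.any(np.diff(rk) < 0):
            raise ValueError("ranks must be non-decreasing")
        if rk.min() < 1 or rk.max() > self.n:
            raise ValueError("ranks must lie in [1, n]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"calb_od": self.calb_od, "rank": self.rank})

    def to_csv(self, path) -> None:
        # %.17g keeps the round trip bit-exact for float64
        self.to_frame().to_csv(path, index=False, lineterminator="\n",
                               float_format="%.17g")

    @classmethod
    def from_csv(cls, path, n: int | None = None) -> "RankTable":
        """Load a two-column ``calb_od,rank`` table.

        ``n`` (subjects behind the table) is not part of the two-column
        format; when omitted it is inferred as ``ceil(max rank)``, which
        is exact unless the largest OD is tied three or more deep.
        """
        frame = pd.read_csv(path, float_precision="round_trip")
        rank = frame["rank"].to_numpy(dtype=float)
        if n is None:
            n = int(np.ceil(rank.max()))
        return cls(calb_od=frame["calb_od"].to_numpy(dtype=float),
                   rank=rank, n=n)


def build_rank_table(calb_values: Sequence[float]) -> RankTable:
    """Rank table over a fitting set: one entry per distinct OD."""
    values = np.asarray(calb_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one CALB value")
    if np.any(values < 0):
        raise ValueError("CALB optical densities must be >= 0")
    ranks = midrank_transform(values)
    distinct, first_idx = np.unique(values, return_index=True)
    return RankTable(calb_od=distinct, rank=ranks[first_idx], n=values.size)


def rank_lookup(table: RankTable, value: float,
                method: str = "linear") -> float:
    """R(CALB) of a new subject from a fixed rank table.

    Exact matches return the stored midrank.  Values between two table
    entries use the nearest entry's rank (``method="closest"``) or a
    linearly interpolated rank (``method="linear"``).  Values outside
    the table's range clamp to the extreme rank.
    """
    if value < 0:
        raise ValueError("CALB value must be >= 0")
    if method not in ("closest", "linear"):
        raise ValueError("method must be closest|linear")
    od, rk = table.calb_od, table.rank
    if value <= od[0]:
        return float(rk[0])
    if value >= od[-1]:
        return float(rk[-1])
    hi = int(np.searchsorted(od, value))
    if od[hi] == value:
        return float(rk[hi])
    lo = hi - 1
    if method == "closest":
        # equidistant values round toward the higher entry
        return float(rk[hi] if value - od[lo] >= od[hi] - value else rk[lo])
    frac = (value - od[lo]) / (od[hi] - od[lo])
    return float(rk[lo] + frac * (rk[hi] - rk[lo]))


@dataclass(frozen=True)
class LogisticModel:
    """Fitted age-adjusted logistic model, with rank table for model 2."""

    model: int
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    converged: bool
    n_case: int
    n_control: int
    rank_table: RankTable | None = None
    diagnostics: str = ""

    def __post_init__(self) -> None:
        expected = MODEL1_TERMS if self.model == 1 else MODEL2_TERMS
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if tuple(self.coefficients) != expected:
            raise ValueError(f"model {self.model} needs terms {expected}")
        if self.model == 2 and self.rank_table is None and self.converged:
            raise ValueError("model 2 requires a rank table")

    @property
    def terms(self) -> tuple[str, ...]:
        return MODEL1_TERMS if self.model == 1 else MODEL2_TERMS

    def to_json(self, path) -> None:
        payload = {
            "model": self.model,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "diagnostics": self.diagnostics,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _design_matrix(records: Sequence[SubjectRecord], model: int
                   ) -> tuple[np.ndarray, np.ndarray, RankTable | None]:
    y = np.array([1.0 if r.is_case else 0.0 for r in records])
    age = np.array([r.age for r in records])
    fobt = np.array([1.0 if r.fobt_positive else 0.0 for r in records])
    cols = [np.ones(len(records)), age, fobt]
    table = None
    if model == 2:
        calb = np.array([r.calb_od for r in records])
        cols.append(midrank_transform(calb))
        table = build_rank_table(calb)
    return np.column_stack(cols), y, table


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
               tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float]:
    """Bias-reduced (Jeffreys-penalised) logistic fit by Newton iteration.

    Used only when requested; it keeps estimates finite under complete
    separation at the cost of a small shrinkage toward zero.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        WX = X * w[:, None]
        info = X.T @ WX
        info_inv = np.linalg.pinv(info)  # pinv tolerates collinear columns
        h = np.einsum("ij,jk,ik->i", WX, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        norm = float(np.max(np.abs(step)))
        if norm > 5.0:  # damp early overshoot far from the optimum
            step *= 5.0 / norm
        beta = beta + step
        if norm < tol:
            break
    eta = X @ beta
    with np.errstate(all="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    w = p * (1.0 - p)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov)), ll


def fit_logistic(records: Sequence[SubjectRecord], model: int,
                 firth: bool = False,
                 start_params: np.ndarray | None = None) -> LogisticModel:
    """Maximum-likelihood fit of model 1 or model 2.

    Perfect separation is reported as ``converged=False`` with a
    diagnostic message rather than silently penalised; pass
    ``firth=True`` for a bias-reduced fit that stays finite.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    n_case = sum(1 for r in records if r.is_case)
    n_control = len(records) - n_case
    if n_case == 0 or n_control == 0:
        raise ValueError("need at least one case and one control")
    X, y, table = _design_matrix(records, model)
    terms = MODEL1_TERMS if model == 1 else MODEL2_TERMS

    if firth:
        beta, se, ll = _firth_fit(X, y)
        return LogisticModel(
            model=model,
            coefficients=dict(zip(terms, map(float, beta))),
            standard_errors=dict(zip(terms, map(float, se))),
            log_likelihood=ll, converged=True,
            n_case=n_case, n_control=n_control, rank_table=table,
            diagnostics="firth",
        )

    diagnostics = ""
    converged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=200, tol=1e-10, start_params=start_params)
        separated = any(issubclass(w.category, PerfectSeparationWarning)
                        for w in caught)
    grad = res.model.score(res.params)
    with np.errstate(over="ignore"):
        fitted = 1.0 / (1.0 + np.exp(-(X @ res.params)))
    # complete separation: every fitted probability at its label's boundary
    fully_separated = separated or bool(np.all(np.abs(fitted - y) < 1e-10))
    if fully_separated or not np.all(np.isfinite(res.params)):
        diagnostics = ("perfect separation detected: maximum-likelihood "
                       "estimates diverge; consider firth=True")
    else:
        # score max-norm is the convergence criterion; under
        # quasi-complete separation on a dummy covariate the score still
        # vanishes while that coefficient drifts, which is noted but
        # does not invalidate the fit (the likelihood and the fitted
        # probabilities have converged, exactly as in R's IRLS)
        converged = float(np.max(np.abs(grad))) < 1e-6
        if not converged:
            diagnostics = (f"optimizer did not reach gradient tolerance "
                           f"(max |score| = {np.max(np.abs(grad)):.3g})")
        elif np.any(np.abs(res.params) > 25):
            diagnostics = ("quasi-complete separation suspected: a "
                           "coefficient is at the numerical boundary")
    with np.errstate(all="ignore"):
        se = np.sqrt(np.diag(res.cov_params()))
    return LogisticModel(
        model=model,
        coefficients=dict(zip(terms, map(float, res.params))),
        standard_errors=dict(zip(terms, map(float, se))),
        log_likelihood=float(res.llf), converged=converged,
        n_case=n_case, n_control=n_control, rank_table=table,
        diagnostics=diagnostics,
    )


def _linear_predictor(model: LogisticModel, subject: SubjectRecord,
                      method: str) -> float:
    c = model.coefficients
    eta = c["intercept"] + c["age"] * subject.age \
        + c["fobt"] * (1.0 if subject.fobt_positive else 0.0)
    if model.model == 2:
        if model.rank_table is None:
            raise ValueError("model 2 has no rank table")
        eta += c["rank_calb"] * rank_lookup(model.rank_table,
                                            subject.calb_od, method)
    return eta


def predict_probability(model: LogisticModel, subject: SubjectRecord,
                        method: str = "linear") -> float:
    """P(case) for one subject via the rank-lookup scoring equation."""
    if not model.converged:
        raise ValueError("refusing to predict from a non-converged model: "
                         + model.diagnostics)
    eta = _linear_predictor(model, subject, method)
    return float(1.0 / (1.0 + np.exp(-eta)))


def predict_probabilities(model: LogisticModel,
                          records: Iterable[SubjectRecord],
                          method: str = "linear") -> np.ndarray:
    return np.array([predict_probability(model, r, method) for r in records])
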