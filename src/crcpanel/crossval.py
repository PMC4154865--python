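"""Leave-one-out cross-validation with per-fold cutoff selection, and
external validation of a fitted model on an independent cohort.

Apparent (resubstitution) performance of a diagnostic model is
optimistic.  The LOOCV procedure here removes that optimism the way the
study design prescribes: for every subject, the model — including the
rank table for the CALB term — is refit on the remaining n-1 subjects;
the probability cutoff whose *training* specificity is closest to the
target (default 90%) is selected within the fold; and the held-out
subject is scored and called positive/negative against that fold's
cutoff.  Pooling the held-out probabilities yields the cross-validated
ROC curve, AUC and partial AUC; pooling the held-out calls yields the
cross-validated sensitivity and achieved specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from crcpanel.rank_model import (
    LogisticModel,
    fit_logistic,
    predict_probabilities,
)
from crcpanel.roc import (
    ROCCurve,
    auc,
    empirical_roc,
    partial_auc,
    sensitivity_at_spec_closest,
)
from crcpanel.synthetic import SubjectRecord

__all__ = ["CVResult", "ValidationMetrics", "loocv", "external_validate",
           "fit_total"]


@dataclass(frozen=True)
class CVResult:
    """Out-of-fold probabilities, calls and cross-validated metrics."""

    oof_probabilities: np.ndarray
    oof_calls: np.ndarray
    cv_curve: ROCCurve
    cv_auc: float
    cv_pauc: float
    cv_sensitivity: float
    achieved_specificity: float
    n_folds: int
    failed_folds: tuple[int, ...] = ()


@dataclass(frozen=True)
class ValidationMetrics:
    """Operating-point and area metrics of a model on one dataset."""

    sensitivity: float
    achieved_specificity: float
    threshold: float
    auc: float
    pauc: float
    curve: ROCCurve


def _cutoff_at_target_spec(curve: ROCCurve, target: float) -> float:
    _, _, threshold = sensitivity_at_spec_closest(curve, target)
    return threshold


def loocv(records: Sequence[SubjectRecord], model: int,
          target_spec: float = 0.90,
          pauc_range: tuple[float, float] = (0.90, 1.0),
          lookup: str = "linear") -> CVResult:
    """Leave-one-out cross-validation of model 1 or 2.

    Each fold refits the logistic model (rebuilding the rank table from
    the training fold only for model 2), selects the training cutoff at
    the specificity closest to ``target_spec``, and classifies the
    held-out subject by ``probability >= cutoff``.  The held-out CALB
    value is ranked against the training-fold table with the given
    ``lookup`` method (``linear`` default, ``closest`` available).
    """
    records = list(records)
    n = len(records)
    labels = np.array([r.is_case for r in records])
    if labels.all() or not labels.any():
        raise ValueError("need both cases and controls")
    # warm start from the full-data fit speeds per-fold Newton steps
    full = fit_logistic(records, model)
    start = np.array([full.coefficients[t] for t in full.terms]) \
        if full.converged else None

    oof_prob = np.empty(n)
    oof_call = np.empty(n, dtype=bool)
    failed: list[int] = []
    for i in range(n):
        train = records[:i] + records[i + 1:]
        train_labels = np.delete(labels, i)
        if train_labels.all() or not train_labels.any():
            raise ValueError(f"fold {i}: training data collapses to one class")
        fold_model = fit_logistic(train, model, start_params=start)
        if not fold_model.converged:
            # a fold can separate completely even when the full data do
            # not (e.g. dropping the only marker-negative case); refit
            # bias-reduced so the held-out subject still gets a finite
            # probability, and report the fold id
            failed.append(i)
            fold_model = fit_logistic(train, model, firth=True)
        train_probs = predict_probabilities(fold_model, train, lookup)
        train_curve = empirical_roc(train_probs, train_labels)
        cutoff = _cutoff_at_target_spec(train_curve, target_spec)
        p_i = float(predict_probabilities(fold_model, [records[i]], lookup)[0])
        oof_prob[i] = p_i
        oof_call[i] = p_i >= cutoff

    cv_curve = empirical_roc(oof_prob, labels)
    return CVResult(
        oof_probabilities=oof_prob,
        oof_calls=oof_call,
        cv_curve=cv_curve,
        cv_auc=auc(cv_curve),
        cv_pauc=partial_auc(cv_curve, pauc_range),
        cv_sensitivity=float(oof_call[labels].mean()),
        achieved_specificity=float((~oof_call[~labels]).mean()),
        n_folds=n,
        failed_folds=tuple(failed),
    )


def external_validate(model: LogisticModel,
                      records: Sequence[SubjectRecord],
                      target_spec: float = 0.90,
                      pauc_range: tuple[float, float] = (0.90, 1.0),
                      lookup: str = "linear") -> ValidationMetrics:
    """Score an already-fitted model on a new cohort.

    CALB ranks come from the model's own (frozen) rank table, never from
    re-ranking within the new cohort — exactly how a published scoring
    equation would be applied prospectively.
    """
    records = list(records)
    labels = np.array([r.is_case for r in records])
    probs = predict_probabilities(model, records, lookup)
    curve = empirical_roc(probs, labels)
    sens, spec, thr = sensitivity_at_spec_closest(curve, target_spec)
    return ValidationMetrics(
        sensitivity=sens, achieved_specificity=spec, threshold=thr,
        auc=auc(curve), pauc=partial_auc(curve, pauc_range), curve=curve,
    )


def fit_total(dev_records: Sequence[SubjectRecord],
              val_records: Sequence[SubjectRecord],
              model: int) -> LogisticModel:
    """Refit on the pooled development + validation data.

    The pooled fit is the final model for future subjects; for model 2
    its rank table (built over the pooled CALB values) is the lookup
    table a future subject would be scored against.
    """
    pooled = list(dev_records) + list(val_records)
    if not dev_records or not val_records:
        raise ValueError("both cohorts must be non-empty")
    return fit_logistic(pooled, model)
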