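"""End-to-end study workflow.

``run_study`` executes the full development → internal validation →
external validation → pooled-refit sequence for both nested models and
assembles a machine-readable report:

1. fit model 1 (AGE + FOBT) and model 2 (AGE + FOBT + R(CALB)) on the
   development cohort and record apparent ROC metrics;
2. leave-one-out cross-validate both models on the development cohort
   (per-fold cutoff at the training specificity closest to the target);
3. apply the development-fitted models to the validation cohort;
4. refit both models on the pooled total set — the final scoring
   equation — and export its rank table;
5. compare model 2 against model 1 (DeLong AUC increase, RI in cases
   and controls, NRI) on each requested dataset.

The report is a plain nested dict that serializes to deterministic JSON
(sorted keys, full float precision); probabilities and proportions stay
on the 0-1 scale — percentages appear only in human-readable summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from crcpanel.crossval import external_validate, fit_total, loocv
from crcpanel.group_stats import (
    kruskal_wallis,
    pearson_chi_square,
    wilcoxon_rank_sum,
)
from crcpanel.rank_model import (
    LogisticModel,
    fit_logistic,
    predict_probabilities,
)
from crcpanel.reclass import reclassification
from crcpanel.roc import (
    auc,
    delong_test,
    empirical_roc,
    partial_auc,
    placement_values,
    sensitivity_at_spec_closest,
)
from crcpanel.synthetic import (
    FOBT_CUTOFF_NG_ML,
    SITES,
    T_STAGES,
    SubjectRecord,
)

__all__ = ["StudyConfig", "StudyResult", "fobt_binarize", "run_study",
           "write_report"]

SCHEMA_VERSION = "1.0"


def fobt_binarize(fobt_ng_ml: float, cutoff: float = FOBT_CUTOFF_NG_ML) -> bool:
    """FOBT positivity call; the cutoff itself counts as positive."""
    if fobt_ng_ml < 0:
        raise ValueError("fobt_ng_ml must be >= 0")
    return fobt_ng_ml >= cutoff


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the full workflow, echoed verbatim into the report."""

    target_spec: float = 0.90
    pauc_range: tuple[float, float] = (0.90, 1.0)
    fobt_cutoff: float = FOBT_CUTOFF_NG_ML
    rank_method: str = "linear"  # closest|linear
    comparison_datasets: tuple[str, ...] = ("development", "validation",
                                            "total")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rank_method not in ("closest", "linear"):
            raise ValueError("rank_method must be closest|linear")
        for d in self.comparison_datasets:
            if d not in ("development", "validation", "total"):
                raise ValueError(f"unknown comparison dataset {d!r}")


@dataclass(frozen=True)
class StudyResult:
    """Report dict plus the fitted model objects for further use."""

    report: dict
    dev_models: dict[int, LogisticModel]
    total_models: dict[int, LogisticModel]


def _auc_ci(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    v10, v01 = placement_values(probs, labels)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    a = float(v10.mean())
    half = 1.96 * float(np.sqrt(max(var, 0.0)))
    return (a - half, a + half)


def _apparent_block(model: LogisticModel, records: Sequence[SubjectRecord],
                    config: StudyConfig) -> dict:
    labels = np.array([r.is_case for r in records])
    probs = predict_probabilities(model, records, config.rank_method)
    curve = empirical_roc(probs, labels)
    sens, spec, thr = sensitivity_at_spec_closest(curve, config.target_spec)
    lo, hi = _auc_ci(probs, labels)
    return {
        "sensitivity": sens,
        "achieved_specificity": spec,
        "threshold": thr,
        "auc": auc(curve),
        "auc_ci_95": [lo, hi],
        "pauc": partial_auc(curve, config.pauc_range),
    }


def _median_range(values: np.ndarray) -> dict:
    return {"median": float(np.median(values)),
            "min": float(values.min()), "max": float(values.max()),
            "n": int(values.size)}


def _descriptive_block(records: Sequence[SubjectRecord]) -> dict:
    """Summary table of one cohort with the usual group tests."""
    cases = [r for r in records if r.is_case]
    ctrls = [r for r in records if not r.is_case]
    case_calb = np.array([r.calb_od for r in cases])
    ctrl_calb = np.array([r.calb_od for r in ctrls])
    case_fobt = np.array([r.fobt_positive for r in cases])
    ctrl_fobt = np.array([r.fobt_positive for r in ctrls])

    block = {
        "n_case": len(cases),
        "n_control": len(ctrls),
        "age_case_mean": float(np.mean([r.age for r in cases])),
        "age_control_mean": float(np.mean([r.age for r in ctrls])),
        "calb_case": _median_range(case_calb),
        "calb_control": _median_range(ctrl_calb),
        "calb_case_vs_control_p": wilcoxon_rank_sum(case_calb, ctrl_calb).p_value,
        "fobt_positive_case": int(case_fobt.sum()),
        "fobt_positive_control": int(ctrl_fobt.sum()),
    }
    fobt_table = np.array([
        [int(case_fobt.sum()), len(cases) - int(case_fobt.sum())],
        [int(ctrl_fobt.sum()), len(ctrls) - int(ctrl_fobt.sum())],
    ])
    if np.all(fobt_table.sum(axis=0) > 0):
        block["fobt_case_vs_control_p"] = pearson_chi_square(fobt_table).p_value

    by_stage = {s: [r for r in cases if r.t_stage == s] for s in T_STAGES}
    stages_present = [s for s in T_STAGES if by_stage[s]]
    block["by_stage"] = {
        s: {
            "calb": _median_range(np.array([r.calb_od for r in by_stage[s]])),
            "fobt_positive": int(sum(r.fobt_positive for r in by_stage[s])),
            "n": len(by_stage[s]),
        }
        for s in stages_present
    }
    if len(stages_present) >= 2:
        block["calb_by_stage_p"] = kruskal_wallis(
            [[r.calb_od for r in by_stage[s]] for s in stages_present]).p_value
        stage_counts = np.array([
            [sum(r.fobt_positive for r in by_stage[s]),
             sum(not r.fobt_positive for r in by_stage[s])]
            for s in stages_present])
        if np.all(stage_counts.sum(axis=0) > 0):
            block["fobt_by_stage_p"] = pearson_chi_square(stage_counts).p_value

    by_site = {s: [r for r in cases if r.site == s] for s in SITES}
    sites_present = [s for s in SITES if by_site[s]]
    block["by_site"] = {
        s: {
            "calb": _median_range(np.array([r.calb_od for r in by_site[s]])),
            "fobt_positive": int(sum(r.fobt_positive for r in by_site[s])),
            "n": len(by_site[s]),
        }
        for s in sites_present
    }
    if len(sites_present) == 2:
        block["calb_by_site_p"] = wilcoxon_rank_sum(
            [r.calb_od for r in by_site["right"]],
            [r.calb_od for r in by_site["left"]]).p_value
    return block


def _delong_dict(res) -> dict:
    return {
        "auc_model_1": res.auc_1, "auc_model_2": res.auc_2,
        "delta_auc": res.delta, "variance_delta": res.variance_delta,
        "z": res.z, "p_value": res.p_value,
        "auc_1_ci_95": list(res.ci_95_auc_1),
        "auc_2_ci_95": list(res.ci_95_auc_2),
        "degenerate": res.degenerate,
    }


def _reclass_dict(res) -> dict:
    return {k: getattr(res, k) for k in (
        "p_up_case", "p_down_case", "p_up_ctrl", "p_down_ctrl",
        "ri_case", "ri_ctrl", "nri", "z_case", "z_ctrl", "z_nri",
        "p_case", "p_ctrl", "p_nri", "n_case", "n_control")}


def _model_dict(model: LogisticModel) -> dict:
    return {
        "model": model.model,
        "coefficients": model.coefficients,
        "standard_errors": model.standard_errors,
        "log_likelihood": model.log_likelihood,
        "converged": model.converged,
        "n_case": model.n_case,
        "n_control": model.n_control,
    }


def run_study(dev_records: Sequence[SubjectRecord],
              val_records: Sequence[SubjectRecord],
              config: StudyConfig = StudyConfig()) -> StudyResult:
    """Run the whole workflow; see the module docstring for the stages."""
    dev_records = list(dev_records)
    val_records = list(val_records)
    total_records = dev_records + val_records

    dev_models = {m: fit_logistic(dev_records, m) for m in (1, 2)}
    total_models = {m: fit_logistic(total_records, m) for m in (1, 2)}
    for m, fitted in {**dev_models, **total_models}.items():
        if not fitted.converged:
            raise RuntimeError(
                f"model {fitted.model} fit failed: {fitted.diagnostics}")

    performance: dict = {
        "development_apparent": {}, "development_loocv": {},
        "validation": {}, "total_apparent": {},
    }
    for m in (1, 2):
        key = f"model_{m}"
        performance["development_apparent"][key] = _apparent_block(
            dev_models[m], dev_records, config)
        cv = loocv(dev_records, m, config.target_spec, config.pauc_range,
                   config.rank_method)
        cv_curve = cv.cv_curve
        performance["development_loocv"][key] = {
            "sensitivity": cv.cv_sensitivity,
            "achieved_specificity": cv.achieved_specificity,
            "auc": cv.cv_auc,
            "auc_ci_95": list(_auc_ci(
                cv.oof_probabilities,
                np.array([r.is_case for r in dev_records]))),
            "pauc": cv.cv_pauc,
            "n_folds": cv.n_folds,
        }
        ext = external_validate(dev_models[m], val_records,
                                config.target_spec, config.pauc_range,
                                config.rank_method)
        performance["validation"][key] = {
            "sensitivity": ext.sensitivity,
            "achieved_specificity": ext.achieved_specificity,
            "threshold": ext.threshold,
            "auc": ext.auc,
            "pauc": ext.pauc,
        }
        performance["total_apparent"][key] = _apparent_block(
            total_models[m], total_records, config)

    datasets = {
        "development": (dev_models, dev_records),
        "validation": (dev_models, val_records),
        "total": (total_models, total_records),
    }
    comparisons = {}
    for name in config.comparison_datasets:
        models, records = datasets[name]
        labels = np.array([r.is_case for r in records])
        p1 = predict_probabilities(models[1], records, config.rank_method)
        p2 = predict_probabilities(models[2], records, config.rank_method)
        comparisons[name] = {
            "delong": _delong_dict(delong_test(p1, p2, labels)),
            "reclassification": _reclass_dict(
                reclassification(p1, p2, labels)),
        }

    report = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "target_spec": config.target_spec,
            "pauc_range": list(config.pauc_range),
            "fobt_cutoff": config.fobt_cutoff,
            "rank_method": config.rank_method,
            "comparison_datasets": list(config.comparison_datasets),
            "seed": config.seed,
        },
        "descriptive": {
            "development": _descriptive_block(dev_records),
            "validation": _descriptive_block(val_records),
        },
        "models": {
            "development": {f"model_{m}": _model_dict(dev_models[m])
                            for m in (1, 2)},
            "total": {f"model_{m}": _model_dict(total_models[m])
                      for m in (1, 2)},
        },
        "performance": performance,
        "comparisons": comparisons,
        "final_model": {
            **_model_dict(total_models[2]),
            "rank_table_entries": int(total_models[2].rank_table.calb_od.size),
        },
    }
    return StudyResult(report=report, dev_models=dev_models,
                       total_models=total_models)


def write_report(report: dict, path) -> None:
    """Deterministic JSON serialization (sorted keys, '\\n' newline)."""
    with open(path, "w", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
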