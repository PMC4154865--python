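# crcpanel

Statistical toolkit for building and validating a colorectal-cancer (CRC)
prediction model that combines two stool markers: the immunochemical fecal
occult blood test (FOBT, positive at ≥ 100 ng Hb/ml) and fecal calgranulin B
(CALB, a calprotectin subunit measured as western-blot optical density).
It is written for biostatisticians and screening researchers who need the
whole modelling pipeline — not just a fitted curve — as reusable, tested
code.

## The model

CALB optical densities are zero-inflated and heavily right-skewed, so the
marker enters the logistic model through its midrank rather than its raw
value.  Two nested, age-adjusted models are compared:

```
model 1:  logit P(CRC) = β₀ + β₁·AGE + β₂·FOBT
model 2:  logit P(CRC) = β₀ + β₁·AGE + β₂·FOBT + β₃·R(CALB)
```

where `FOBT ∈ {0,1}` and `R(CALB)` is the subject's midrank among the
fitting set's CALB values.  A fitted model 2 carries its **rank table**
(sorted distinct OD values with midranks); a future subject's `R(CALB)` is
read off that table by exact match, nearest entry, or linear interpolation,
clamped at the extremes.  Because only ranks enter, the fit is invariant
under any strictly increasing transformation of the marker.

Around that core the package provides:

* **ROC analysis** — empirical curves, trapezoidal AUC (equal to the
  tie-adjusted Mann–Whitney probability), partial AUC over the 90–100%
  specificity window (maximum 0.10), sensitivity at the specificity
  closest to a target, and the DeLong placement-value test for the
  increase in AUC between the nested models.
* **Leave-one-out cross-validation** — per-fold refit (rank table rebuilt
  from the training fold only), per-fold probability cutoff at the
  training specificity closest to 90%, out-of-fold calls and a
  cross-validated ROC/AUC/pAUC, plus external validation on an
  independent cohort and a pooled "total set" refit for the final
  scoring equation.
* **Reclassification** — category-free reclassification improvement in
  cases and controls and the net reclassification improvement (NRI) with
  asymptotic z-tests.
* **Design calculations** — exact one-sided Clopper–Pearson lower
  confidence limits and the assurance probability that the limit clears a
  floor, by exact binomial enumeration, with sample-size search and
  dropout inflation.
* **Synthetic cohorts** — a generator calibrated to the published summary
  structure of a 81-case/51-control development set and a
  94-case/100-control validation set (zero-inflated CALB, stage-dependent
  FOBT positivity, age imbalance), so the full pipeline runs without
  patient-level data.

## Worked example

```bash
crcpanel simulate --cohort development --seed 9  --out dev.csv
crcpanel simulate --cohort validation  --seed 10 --out val.csv
crcpanel report --dev dev.csv --val val.csv \
    --out report.json --ranktable ranks.csv
```

prints

```
development_apparent model_1: sens 0.8272 at spec 0.9020, AUC 0.9480, pAUC 0.0791
development_apparent model_2: sens 0.9383 at spec 0.9020, AUC 0.9627, pAUC 0.0844
development_loocv model_1: sens 0.8148 at spec 0.9020, AUC 0.9395, pAUC 0.0759
development_loocv model_2: sens 0.9136 at spec 0.9020, AUC 0.9513, pAUC 0.0783
validation model_1: sens 0.6383 at spec 0.9000, AUC 0.8818, pAUC 0.0535
validation model_2: sens 0.8298 at spec 0.9000, AUC 0.9345, pAUC 0.0704
```

Reading the development rows: at the operating point whose specificity is
closest to 90% (here 90.2%, i.e. 46/51 simulated controls negative), the
FOBT-only model calls 82.7% of cases positive, and adding the CALB rank
raises that to 93.8%.  The LOOCV rows are the bias-corrected versions of
the same quantities — slightly lower, as resubstitution optimism is
removed — and the validation rows apply the development-fitted models,
including their frozen rank table, to the independent cohort.  `report.json`
additionally contains the DeLong ΔAUC test and the RI/NRI comparison of
the two models on the development, validation and pooled sets, and
`ranks.csv` is the final pooled rank table used to score future subjects.

The same machinery is available as a library:

```python
from crcpanel import default_config, generate_cohort, fit_logistic, loocv

dev = generate_cohort(default_config("development", seed=9))
model = fit_logistic(dev, model=2)
cv = loocv(dev, model=2)         # per-fold cutoff at 90% specificity
print(cv.cv_sensitivity, cv.cv_auc)
```

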