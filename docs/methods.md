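# Methods

This note records the statistical procedures implemented in `crcpanel`,
the modelling assumptions behind them, and the choices made where the
design was genuinely open.

## Rank-transform logistic modelling

Fecal calgranulin B (CALB) optical densities have a point mass at zero
(many subjects with no detectable band) and a long right tail, so raw
values violate every distributional convenience of logistic regression.
The package therefore replaces the raw OD by its midrank (ties receive
the average of their rank block) computed over the fitting set, and fits

    logit P(case) = β₀ + β₁·AGE + β₂·FOBT (+ β₃·R(CALB))

by maximum likelihood.  Ranks are kept on the raw 1..n scale, not
rescaled to [0,1]; the accompanying rank table maps each distinct OD to
its midrank so that a future subject can be scored without re-ranking.
Values between table entries are resolved by the nearest entry or by
linear interpolation (configurable, linear by default); values outside
the table clamp to the extreme ranks, which preserves monotonicity of
the score in the marker.  Age enters linearly.

Fitting uses iteratively reweighted least squares (statsmodels GLM with
a binomial family), the same algorithm as R's `glm`.  Convergence is
declared when the score (gradient) max-norm falls below 1e-6.  Two
degenerate regimes are handled explicitly:

* **Quasi-complete separation.**  When every FOBT-positive subject in a
  fitting set is a case — which happens easily when controls have a
  positivity rate of ~2% or 0% — the FOBT coefficient's MLE is infinite,
  but the likelihood and all fitted probabilities converge.  The fit is
  accepted (the score criterion is met) with a diagnostic noting the
  boundary coefficient.
* **Complete separation.**  If every fitted probability reaches its
  label's boundary the fit is reported as non-converged and prediction
  is refused; a Firth-style bias-reduced fit (Jeffreys-penalised score,
  damped Newton with pseudo-inverse) is available via `firth=True`.

## Validation workflow

The workflow mirrors how two-cohort diagnostic studies are analysed:

1. **Apparent** performance of both models on the development cohort.
2. **Internal validation** by leave-one-out cross-validation: each fold
   refits the model on n−1 subjects (the rank table is rebuilt from the
   training fold only), chooses the probability cutoff whose training
   specificity is closest to the 90% target, and classifies the held-out
   subject by `probability ≥ cutoff`, ranking its CALB against the
   training table (linear interpolation by default; the study design
   leaves the left-out ranking rule unstated, so it is configurable).
   Out-of-fold probabilities form the cross-validated ROC/AUC/pAUC;
   out-of-fold calls give the cross-validated sensitivity and achieved
   specificity.  A fold that separates completely is refit with the
   Firth estimator so its held-out subject still receives a finite
   probability; such folds are reported by id.
3. **External validation** of the frozen development models (including
   their rank table) on the independent cohort.
4. **Total-set refit** on the pooled cohorts; this pooled model and its
   pooled rank table are the final scoring equation.

Model 2's incremental value over model 1 is assessed by the DeLong
placement-value test on the paired AUCs and by category-free
reclassification: RI(cases) = P(probability up) − P(down),
RI(controls) = P(down) − P(up), NRI = their sum, each with the
asymptotic variance (p_up + p_down − (p_up − p_down)²)/n and a two-sided
normal test.  Subjects with exactly unchanged probabilities count in
neither direction, matching the strict higher/lower definition.  Because
the pipeline cannot know which dataset a published comparison used, it
computes the comparison on the development, validation and pooled sets
and labels each.

Numerical conventions: a subject is called positive when its score is at
or above the threshold; ties between case and control scores count one
half in the AUC (Mann–Whitney convention, which the trapezoidal area
reproduces exactly); "specificity closest to target" breaks exact ties
toward the higher specificity (the conservative screening choice); the
partial AUC is unnormalized (maximum = window width, 0.10 for 90–100%)
with linear interpolation at the window boundaries, and McClish
standardization is available by flag; the FOBT cutoff of 100 ng Hb/ml is
inclusive (100 is positive).

## Design calculations

Assurance calculations use the exact one-sided Clopper–Pearson lower
limit (beta quantile inversion of the binomial tail; k = 0 gives 0) and
enumerate the binomial distribution of the observed count — no normal
approximation.  One-sided limits are the default because the design
question concerns a lower confidence bound alone.  The assurance is not
exactly monotone in n: on the grid n = 20..80 (true 0.90, floor 0.75)
the exact-binomial sawtooth produces local decreases of up to 0.028, so
the smallest-n search scans upward to a cap and returns the first
crossing rather than assuming monotonicity.  The dropout inflation uses
the ceiling rule: the smallest m with m·(1 − rate) ≥ n.

## Synthetic cohorts

The generator emulates the marginal structure such a two-marker study
reports, with one PCG64 stream per cohort seeded once:

* **CALB**: a zero-inflated, upper-truncated log-normal.  Zero masses
  are 0.15 (cases) and 0.65/0.70 (controls; a zero mass above one half
  forces the zero group median seen in real control data).  The
  log-normal median for cases is solved numerically so that the mixture
  median equals the published group median (2557.5 development, 2968.6
  validation) under truncation at the published range maximum; for the
  validation cases the solution lies above the truncation bound, i.e.
  the distribution is strongly right-truncated, consistent with a group
  median at 64% of the range maximum.  Control positive parts are
  centred high (median 1800/1700, σ 0.85) rather than low: the marker
  alone should discriminate only modestly (about 0.79 sensitivity at
  0.77 specificity, AUC ≈ 0.83 in large samples), as reported for CALB
  as a single marker.
* **FOBT**: binary by stage (cases: 1/14, 6/10, 26/47, 9/10 for T1–T4
  in the development configuration, matching a stage-weighted 42/81
  overall; controls: 1/51 and 0/100).  An optional continuous mode
  draws ng/ml values from exponential tails on either side of the
  100 ng/ml cutoff for cutoff-logic tests.
* **Ages**: normal with the published means/SDs, truncated at 18 years.
* **Stage and site**: multinomial with the published compositions;
  controls carry neither.

CALB and FOBT are drawn independently within a subject given group and
stage; the true within-subject dependence of the two markers is unknown
from published summaries, so none is imposed.  The generator does not
model densitometry noise, batch effects, or symptom covariates.  Passing
tests on these cohorts demonstrate that the procedures are correct and
calibrated under a realistic marginal structure; they cannot demonstrate
how the markers co-vary in real stool samples, nor the models' true
clinical operating characteristics.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to make their Monte Carlo error
small relative to the asserted bands: DeLong variance is compared with a
2000-replicate bootstrap at 50+50 and null calibration uses 1000
simulations; NRI null calibration uses 500 nested-null fits at n = 160;
the LOOCV optimism check averages 100 study-sized (81/51) cohorts.

## Known limitations

* The asymptotic NRI test is anti-conservative in small samples; its
  type-I error is only required to stay within a loose [0.02, 0.10]
  band in the null-calibration test.
* Out-of-fold LOOCV scoring is pessimistic under a pure null: with no
  signal at n = 200 the cross-validated AUC centres near 0.42, not 0.50.
  This is a property of leave-one-out scoring (the held-out subject
  systematically falls on the wrong side of a noise fit), not an
  implementation artifact; the procedure is used for optimism
  correction, where only the direction of the bias matters.
* The rank-table CSV stores only (OD, midrank) pairs; the number of
  subjects behind the table is inferred on load as the ceiling of the
  largest midrank, exact unless the largest OD is tied three or more
  deep.
* Categorical (threshold-based) NRI and smoothed/binormal ROC fitting
  are out of scope.
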