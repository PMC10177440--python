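# Methods

## Statistical model

A patient's record carries a binary 5-year endpoint (death from, or
detection of, UM metastasis within 5 years of primary treatment), an ordinal
primary-tumour stage (I < IIA < IIB < IIIA < IIIB < IIIC), a chromosome-3
status (monosomy / disomy / unknown), and three continuous 5-year MAM score
channels representing three information scenarios: `mam5_full` (all inputs),
`mam5_nochr3` (chromosome-3 result unavailable) and `mam5_nogenetics` (all
genetic inputs unavailable). A stratification strategy maps a record to a
binary surveillance decision; its accuracy is summarised by the usual
confusion-matrix functionals with the endpoint as reference standard.

### Accuracy statistics

- Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), each with an exact
  two-sided Clopper–Pearson interval: lower = BetaInv(α/2; k, n−k+1),
  upper = BetaInv(1−α/2; k+1, n−k), with the conventional endpoints at
  k = 0 and k = n. Exactness guarantees at least nominal coverage; the test
  suite checks both the Beta-quantile identity against a binomial-tail
  bisection oracle (to 1e−9) and empirical coverage in simulation.
- PPV/NPV/surveillance fraction come either from observed counts or, in
  *scenario mode*, from (s, c, π) by Bayes' rule:
  PPV = sπ/(sπ + (1−c)(1−π)), NPV = c(1−π)/((1−s)π + c(1−π)),
  surveillance = sπ + (1−c)(1−π). Scenario mode with whole-percent inputs
  is what report tables of this kind print, so the package reproduces those
  tables without patient-level data. When a subgroup evaluation leaves a
  predicted margin empty (a rule that enrols everyone in that subgroup has
  no low-risk patients), the affected predictive value is reported as NaN
  rather than an error, because the remaining columns are still meaningful.
- The ROC curve is empirical: every distinct observed score acts as an
  inclusive threshold, plus the degenerate (0,0) and (1,1) points. The AUC
  is trapezoidal, which on this curve equals the tie-corrected Mann–Whitney
  statistic (ties count one half); the test suite asserts the equality to
  1e−12 against an O(mn) pair-counting oracle. The AUC interval and the
  paired comparison of two score channels measured on the same patients use
  DeLong's structural components: per positive i, V10_i is the mean
  Mann–Whitney kernel against all negatives (computed via midranks in
  O(N log N)), and symmetrically V01_j per negative;
  var(AUC_a − AUC_b) = (S10_aa + S10_bb − 2S10_ab)/m + (S01 terms)/n.
  The implementation was cross-checked against an independent
  implementation (R pROC's paired `roc.test` and DeLong `ci.auc`) on a
  frozen 40-record fixture, agreeing to ~1e−10, and against a paired
  bootstrap (variance within 15%) and a simulated null (uniform p-values)
  in the suite. Identical curves short-circuit to statistic 0, p = 1;
  a zero variance with unequal AUCs raises instead of dividing by zero.
  All p-values are two-sided; families of comparisons are adjusted by Holm
  step-down (via `statsmodels.multipletests`), and the executed family is
  recorded in the run log.
- `threshold_for_sensitivity` returns the largest threshold whose inclusive
  sensitivity meets the target, i.e. the k-th largest positive score with
  k = ⌈target·m⌉. Because sensitivity and specificity trade off
  monotonically along the threshold axis, this threshold is also the most
  specific one meeting the target. If only threshold 0 attains the target
  (positives scored exactly 0), the result is flagged `degenerate`.

### Threshold semantics

All threshold comparisons are inclusive (score ≥ t enrols, stage ≥ cut
enrols), matching the "MAM ≥ x" notation these rules are quoted in. Scores
are probabilities in [0, 1]; rules quoted on a 0–100 scale should be
normalised at ingestion (MAM ≥ 5 → 0.05).

## Impact model

For a population N with endpoint incidence π and a strategy with
sensitivity s and specificity c: TP = round(Nπs), FN = round(Nπ(1−s)),
TN = round(N(1−π)c), FP = round(N(1−π)(1−c)), each independently rounded to
the nearest whole patient (half away from zero). If independent rounding
breaks the population total — possible only when fractions sit at one half —
the most ambiguous cell is adjusted and the report flagged. Scan totals are
10·FP + 3·TP over the 5-year horizon (negatives receive none) and costs are
*truncated* to whole pounds; truncation rather than rounding is the
convention that makes 310 ultrasound scans at £135.09 come to £41,877.
Between-strategy deltas difference the already-rounded cells — rounding
first and differencing second is the only order consistent with the
published headline figures — and scans avoided count only false-positive
scans; when the two strategies' sensitivities differ the delta deliberately
excludes the change in true-positive scan load and the output flags that
the comparison is not sensitivity-matched. Default scenario: N = 200,
π = 0.28, MRI £211.24, ultrasound £135.09 (2020/21 NHS England national
schedule).

## Synthetic cohort generator

Cohorts of this kind are confidential, so the generator emulates the
published statistical structure of a large UK ocular-oncology case mix
(n = 1047, 723 with a chromosome-3 result):

1. Subgroup membership ~ Bernoulli(723/1047).
2. Latent true endpoint probability p from a two-component Beta mixture per
   subgroup: a low-risk bulk plus a high-risk tail. Tested:
   0.479·Beta(1.0, 15.5) + 0.521·Beta(2.15, 1.45) (mean 0.34). Untested:
   0.88·Beta(1.0, 10.0) + 0.12·Beta(2.5, 2.5) (mean 0.14, so untested
   patients are lower-risk with smaller tumours). Overall incidence
   723/1047·0.34 + 324/1047·0.14 ≈ 0.278.
3. Endpoint ~ Bernoulli(p). The full-information score *is* p (perfect
   calibration): no score-error model is published, and this choice makes
   the score's AUC a pure function of the mixture, so calibration has one
   moving part.
4. Degraded channels are logit-space Gaussian jitter:
   expit(logit p + σε), with σ = 0.85 for the no-chromosome-3 channel and
   σ = 1.25 for the no-genetics channel. Jitter keeps scores in [0, 1],
   leaves σ = 0 an exact identity, and one dispersion per channel tunes the
   AUC loss. For untested patients the no-chromosome-3 value is also the
   full-information value (that is all the information they have).
5. Chromosome-3 status of tested patients is monosomy with probability
   expit(α + 1.5·logit p); α is solved by quadrature + root-finding at
   generation time so that about 50% of tested tumours are monosomy, the
   fraction reported for choroidal melanomas.
6. Stage cuts a noisy copy of p (logit jitter, σ = 1.4) at fixed cutpoints
   (0.0408, 0.2083, 0.5976, 0.8669, 0.9598), the noisy-copy quantiles at
   cumulative fractions (0.29, 0.56, 0.78, 0.91, 0.97), so stage ≥ IIA
   enrols ≈71% and ≥ IIB ≈44% of patients and the distribution is skewed to
   low stages; a further ±1 misassignment with probability 0.05 models
   staging error.
7. Covariates (age, sex, tumour diameter and height, ciliary-body
   involvement, extraocular extension) are simple parametric draws matched
   to the published medians/ranges, correlated with latent risk and with
   untested tumours ~1.5 mm smaller. They exist to exercise the eligibility
   filter and CSV schema; no downstream statistic uses them.

All draws come from a single seeded generator, one vectorised draw per field
in a fixed order, so a given configuration and seed reproduce the cohort CSV
byte for byte.

### Calibration

Mixture shapes and noise dispersions were chosen by grid search against
Monte-Carlo oracles (expected AUC computed by weighting each latent draw as
positive with weight p and negative with 1−p) and then frozen. At the
defaults, over 200 replicate cohorts of n = 1047 the package's own checks
find mean incidence ≈ 0.278, mean AUC ≈ 0.885 (full score), ≈ 0.843
(no-genetics), ≈ 0.787 (no-chromosome-3 score within the untested
subgroup), monosomy fraction ≈ 0.50, and a stage ≥ IIA operating point near
(0.95, 0.38) — the calibration targets for each quantity.

### What the generator does and does not emulate

It reproduces subgroup structure, incidences, score discrimination and its
degradation, stage skew and the monosomy fraction — enough for every
downstream statistic to be exercised at realistic operating points. It does
**not** model time-to-event structure (the endpoint is a 5-year binary),
real covariate–risk joint distributions, informative missingness beyond the
two-subgroup contrast, correlated training-set membership with external
prognostic models, or miscalibrated scores (the full channel is perfectly
calibrated by construction). Passing simulation-based tests therefore shows
the *machinery* is correct at the published operating points, not that any
particular clinical dataset would reproduce the published accuracy values.

## Eligibility filter

Raw tables may carry missing covariates and optional `iris_melanoma` /
`followup_5y` flags. A record is excluded (with exactly one logged reason,
first matching rule wins) if it is an iris melanoma; is missing age, sex,
tumour dimensions, ciliary-body involvement or extraocular extension; or
lacks five years of follow-up without an observed endpoint. The raw schema
carries a follow-up-adequacy flag rather than dates; resolving the
follow-up rule from visit dates is out of scope.

## Numerical and design choices

- Report tables round to whole percent; impact counts round to whole
  patients; costs truncate to whole pounds. Library functions always return
  unrounded floats — rounding happens only at the reporting layer.
- The dual-threshold defaults (0.07 tested / 0.045 untested) follow the
  published decision algorithm; both thresholds are ordinary parameters.
- Six stage categories are used; stage labels outside the six are schema
  errors.
- The Holm family in a pipeline run is the set of DeLong comparisons
  actually executed in that run (all three channel pairs by default),
  logged with the run.
- Problem sizes in the test suite (200 replicate cohorts of n = 1047; 500
  null replicates of n = 2000 for the DeLong uniformity check; 5000
  replicates for interval coverage) were chosen to make Monte-Carlo error
  comfortably smaller than the tolerance being checked.

## Known limitations

- The generator's AUC targets are expectations; a single cohort's empirical
  AUC varies by ±0.01–0.03 (and more in the 324-patient subgroup).
- Scenario-mode predictive values with rounded sensitivity/specificity
  inputs reproduce printed report tables, but whether such tables were
  originally derived from raw counts or rounded rates is generally not
  stated; both routes are exposed (`counts` vs scenario mode).
- The impact model prices scans only; it is not an economic evaluation
  (no QALYs, treatment-pathway costs or discounting).
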