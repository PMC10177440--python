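"""Diagnostic accuracy statistics: oracles, boundary cases, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from umstrat import (
    ConfusionCounts,
    DiagnosticsError,
    Strategy,
    clopper_pearson,
    confusion,
    delong_paired,
    empirical_roc,
    evaluate_strategy,
    holm_adjust,
    mann_whitney_auc,
    predictive_values,
    sens_spec,
    threshold_for_sensitivity,
)
from conftest import brute_force_auc

# ---------------------------------------------------------------------------
# confusion


def test_confusion_hand_count():
    c = confusion(np.array([1, 1, 0, 0], bool), np.array([1, 0, 1, 0], bool))
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)


def test_confusion_all_high_has_no_negative_calls():
    c = confusion(np.ones(10, bool), np.arange(10) % 2 == 0)
    assert c.fn == 0 and c.tn == 0


def test_confusion_matches_loop_oracle():
    rng = np.random.default_rng(0)
    dec = rng.random(50) < 0.5
    y = rng.random(50) < 0.3
    c = confusion(dec, y)
    tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for d, e in zip(dec, y):
        tally[("t" if d == e else "f") + ("p" if d else "n")] += 1
    assert (c.tp, c.fp, c.fn, c.tn) == (tally["tp"], tally["fp"], tally["fn"], tally["tn"])


def test_confusion_length_mismatch():
    with pytest.raises(DiagnosticsError):
        confusion(np.ones(3, bool), np.ones(4, bool))


# ---------------------------------------------------------------------------
# Clopper-Pearson


def _cp_bisection(k: int, n: int, level: float) -> tuple[float, float]:
    """Binomial-tail bisection oracle for the exact interval."""
    alpha = 1 - level

    def solve(g, lo, hi):
        # g increasing in p; returns its root by bisection
        for _ in range(200):
            mid = (lo + hi) / 2
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    # lower: P(X >= k | p) = alpha/2 (sf increasing in p)
    lower = 0.0 if k == 0 else solve(lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 0.0, 1.0)
    # upper: P(X <= k | p) = alpha/2 (cdf decreasing in p)
    upper = 1.0 if k == n else solve(lambda p: alpha / 2 - stats.binom.cdf(k, n, p), 0.0, 1.0)
    return lower, upper


@pytest.mark.parametrize("k,n", [(95, 100), (1, 10), (7, 8), (25, 50), (0, 12), (12, 12)])
def test_clopper_pearson_matches_tail_bisection(k, n):
    ci = clopper_pearson(k, n, 0.95)
    lo, hi = _cp_bisection(k, n, 0.95)
    assert ci.lower == pytest.approx(lo, abs=1e-9)
    assert ci.upper == pytest.approx(hi, abs=1e-9)


def test_clopper_pearson_boundaries():
    assert clopper_pearson(10, 10).upper == 1.0
    assert clopper_pearson(0, 10).lower == 0.0


def test_sens_spec_point_estimates():
    counts = ConfusionCounts(tp=53, fp=71, fn=3, tn=73)
    sens, spec = sens_spec(counts)
    assert sens.estimate == pytest.approx(53 / 56)  # ~0.946
    assert spec.estimate == pytest.approx(73 / 144)
    assert sens.lower <= sens.estimate <= sens.upper


def test_sens_spec_empty_margin_errors():
    with pytest.raises(DiagnosticsError, match="endpoint-positive"):
        sens_spec(ConfusionCounts(tp=0, fp=5, fn=0, tn=5))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(k=st.integers(0, 40), n=st.integers(1, 40), level=st.sampled_from([0.9, 0.95, 0.99]))
def test_clopper_pearson_interval_ordering(k, n, level):
    if k > n:
        k = n
    ci = clopper_pearson(k, n, level)
    assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 1.0


# ---------------------------------------------------------------------------
# predictive values


def test_predictive_values_scenario_table_rows():
    """Published-style whole-percent values at prevalence 292/1047."""
    pi = 292 / 1047
    _, npv, _ = predictive_values(sensitivity=0.95, specificity=0.46, prevalence=pi)
    assert round(100 * npv) == 96
    ppv, _, _ = predictive_values(sensitivity=0.95, specificity=0.37, prevalence=pi)
    assert round(100 * ppv) == 37
    _, _, surv = predictive_values(sensitivity=0.95, specificity=0.51, prevalence=pi)
    assert round(100 * surv) == 62


def test_predictive_values_perfect_test():
    ppv, npv, surv = predictive_values(sensitivity=1.0, specificity=1.0, prevalence=0.3)
    assert ppv == 1.0 and npv == 1.0 and surv == pytest.approx(0.3)


def test_predictive_values_scenario_matches_large_population_counts():
    """Bayes formula equals brute-force expected counts at n = 10^6."""
    s, c, pi, n = 0.95, 0.37, 292 / 1047, 10**6
    tp = n * pi * s
    fp = n * (1 - pi) * (1 - c)
    tn = n * (1 - pi) * c
    fn = n * pi * (1 - s)
    ppv, npv, surv = predictive_values(sensitivity=s, specificity=c, prevalence=pi)
    assert ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
    assert npv == pytest.approx(tn / (tn + fn), abs=1e-12)
    assert surv == pytest.approx((tp + fp) / n, abs=1e-12)


def test_predictive_values_counts_mode():
    ppv, npv, surv = predictive_values(ConfusionCounts(tp=53, fp=71, fn=3, tn=73))
    assert ppv == pytest.approx(53 / 124)
    assert npv == pytest.approx(73 / 76)
    assert surv == pytest.approx(124 / 200)


# ---------------------------------------------------------------------------
# ROC / AUC


def test_roc_perfect_separation():
    roc = empirical_roc(np.array([0.9, 0.8, 0.3, 0.1]), np.array([1, 1, 0, 0], bool))
    assert roc.auc == 1.0


def test_roc_ties_only():
    roc = empirical_roc(np.full(10, 0.5), np.arange(10) % 2 == 0)
    assert roc.auc == pytest.approx(0.5)


def test_roc_endpoints_and_monotonicity(default_cohort):
    roc = empirical_roc(default_cohort.df["mam5_full"].to_numpy(), default_cohort.endpoint)
    assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
    assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
    assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
    assert 0.0 <= roc.auc_lower <= roc.auc <= roc.auc_upper <= 1.0


def test_trapezoid_auc_equals_pair_counting():
    rng = np.random.default_rng(1)
    scores = np.round(rng.random(30), 2)  # duplicates force tie handling
    y = rng.random(30) < 0.4
    roc = empirical_roc(scores, y)
    oracle = brute_force_auc(scores, y)
    assert roc.auc == pytest.approx(oracle, abs=1e-12)
    assert mann_whitney_auc(scores, y) == pytest.approx(oracle, abs=1e-12)


def test_auc_label_swap_antisymmetry():
    rng = np.random.default_rng(2)
    scores = np.round(rng.random(40), 2)
    y = rng.random(40) < 0.5
    assert mann_whitney_auc(scores, y) + mann_whitney_auc(scores, ~y) == pytest.approx(1.0, abs=1e-12)


def test_roc_single_class_error():
    with pytest.raises(DiagnosticsError):
        empirical_roc(np.array([0.1, 0.2]), np.array([1, 1], bool))


# ---------------------------------------------------------------------------
# DeLong paired test

# 40-patient fixture with two correlated score channels; reference values
# computed once with an independent implementation of the DeLong machinery
# (R pROC 1.19: roc.test paired DeLong and ci.auc DeLong interval).
_Y = np.array([1,0,1,1,0,0,1,1,0,1,1,1,0,1,0,0,1,0,1,1,
               0,0,1,0,0,0,1,1,1,1,1,0,0,1,1,1,1,0,0,0], bool)
_A = np.array([0.70394,0.183104,0.780051,0.645459,0.067127,0.133773,0.309328,
               0.502522,0.40235,0.266265,0.808435,0.784245,0.648293,0.78141,
               0.555365,0.250692,0.287539,0.090434,0.498995,0.297818,0.524477,
               0.176318,0.762153,0.701395,0.310238,0.541766,0.472996,0.568119,
               0.434199,0.561132,0.962393,0.133593,0.433606,0.312955,0.565584,
               0.549319,0.480252,0.192821,0.309334,0.689588])
_B = np.array([0.949238,0.1637,0.323649,0.804635,0.120336,0.648416,0.816016,
               0.54773,0.910611,0.050899,0.507918,0.366057,0.367151,0.299431,
               0.828815,0.199934,0.128892,0.058658,0.825744,0.782636,0.951336,
               0.979063,0.893795,0.145705,0.019355,0.501445,0.340305,0.44373,
               0.38129,0.572417,0.986286,0.441169,0.295565,0.067009,0.125613,
               0.640302,0.444532,0.860626,0.314118,0.91318])


def test_delong_matches_independent_reference():
    res = delong_paired(_A, _B, _Y)
    assert res.auc_a == pytest.approx(0.762626262626, abs=1e-10)
    assert res.auc_b == pytest.approx(0.527777777778, abs=1e-10)
    assert res.statistic == pytest.approx(2.202333359554, abs=1e-9)
    assert res.p_raw == pytest.approx(0.027641769407, abs=1e-9)
    roc = empirical_roc(_A, _Y)
    assert roc.auc_lower == pytest.approx(0.611687453335, abs=1e-9)
    assert roc.auc_upper == pytest.approx(0.913565071917, abs=1e-9)


def test_delong_identical_scores():
    res = delong_paired(_A, _A, _Y)
    assert res.statistic == 0.0 and res.p_raw == 1.0


def test_delong_variance_matches_paired_bootstrap():
    """DeLong variance of the AUC difference agrees with a 2000-resample
    paired bootstrap within 15% on a 300-record fixture."""
    rng = np.random.default_rng(3)
    n = 300
    z = rng.normal(0, 1.3, n)
    y = rng.random(n) < 1 / (1 + np.exp(-z))
    a = 1 / (1 + np.exp(-(z + 0.7 * rng.normal(size=n))))
    b = 1 / (1 + np.exp(-(z + 1.2 * rng.normal(size=n))))
    res = delong_paired(a, b, y)
    var_delong = ((res.auc_a - res.auc_b) / res.statistic) ** 2
    diffs = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        if y[idx].all() or not y[idx].any():
            continue
        diffs.append(mann_whitney_auc(a[idx], y[idx]) - mann_whitney_auc(b[idx], y[idx]))
    var_boot = np.var(diffs, ddof=1)
    assert abs(var_delong - var_boot) / var_boot < 0.15


def test_delong_degenerate_variance_unequal_aucs():
    y = np.array([1, 1, 0, 0], bool)
    with pytest.raises(DiagnosticsError):
        # constant scores: zero variance but distinct AUCs
        delong_paired(np.array([1.0, 1.0, 0.0, 0.0]), np.array([0.5, 0.5, 0.5, 0.5]), y)


# ---------------------------------------------------------------------------
# Holm


def test_holm_single_p_unchanged():
    assert holm_adjust([0.2]) == pytest.approx([0.2])


def test_holm_hand_example():
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
def test_holm_dominates_raw(ps):
    adj = holm_adjust(ps)
    assert (adj >= np.asarray(ps) - 1e-15).all()
    assert (adj <= 1.0).all()


def test_holm_rejects_out_of_range():
    with pytest.raises(DiagnosticsError):
        holm_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# evaluate_strategy / threshold selection


def test_evaluate_strategy_perfect_separable(tiny_cohort):
    s = Strategy(kind="score_threshold", label="sep", score_field="mam5_full", threshold=0.30)
    summary = evaluate_strategy(tiny_cohort, s, "all")
    assert summary.sensitivity.estimate == 1.0
    assert summary.specificity.estimate == 1.0


def test_evaluate_strategy_equals_manual_filtering(default_cohort):
    s = Strategy(kind="score_threshold", label="t05", score_field="mam5_full", threshold=0.05)
    for subgroup in ("chr3_known", "chr3_unknown"):
        direct = evaluate_strategy(default_cohort, s, subgroup)
        manual = evaluate_strategy(default_cohort.subgroup(subgroup), s, "all")
        assert direct.sensitivity.estimate == manual.sensitivity.estimate
        assert direct.specificity.estimate == manual.specificity.estimate
        assert direct.surveillance_fraction == manual.surveillance_fraction


def test_evaluate_monosomy_surveillance_fraction(default_cohort):
    s = Strategy(kind="monosomy3", label="m3")
    summary = evaluate_strategy(default_cohort, s, "all")
    status = default_cohort.df["chr3_status"]
    expected = ((status != "disomy").sum()) / default_cohort.n
    assert summary.surveillance_fraction == pytest.approx(expected)
    # calibrated case mix puts roughly two thirds of patients under surveillance
    assert 0.60 < summary.surveillance_fraction < 0.72


def test_threshold_for_sensitivity_separable(tiny_cohort):
    res = threshold_for_sensitivity(tiny_cohort, "mam5_full", 1.0)
    assert res.threshold == pytest.approx(0.30)  # minimum positive score
    assert res.sensitivity == 1.0


def test_threshold_for_sensitivity_exhaustive_scan(default_cohort):
    """Returned threshold meets the target and the next larger observed
    score does not."""
    target = 0.95
    res = threshold_for_sensitivity(default_cohort, "mam5_full", target)
    assert res.sensitivity >= target
    scores = default_cohort.df["mam5_full"].to_numpy()
    y = default_cohort.endpoint
    larger = np.unique(scores[scores > res.threshold])
    if len(larger):
        t_next = larger[0]
        sens_next = np.mean(scores[y] >= t_next)
        assert sens_next < target
    # exhaustive-scan oracle: best threshold among all observed scores
    candidates = [t for t in np.unique(scores) if np.mean(scores[y] >= t) >= target]
    assert res.threshold == pytest.approx(max(candidates))


def test_threshold_for_sensitivity_monotone_in_target(default_cohort):
    thresholds = [
        threshold_for_sensitivity(default_cohort, "mam5_full", t).threshold
        for t in (0.99, 0.95, 0.90, 0.80)
    ]
    assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))
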