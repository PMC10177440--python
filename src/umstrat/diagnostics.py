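"""Diagnostic-accuracy statistics for stratification strategies.

Confusion counts, sensitivity/specificity with Clopper–Pearson exact
intervals, predictive values, empirical ROC curves with DeLong AUC
intervals, the DeLong paired test for correlated AUCs, Holm step-down
multiplicity adjustment, matched-sensitivity threshold selection, and
subgroup-restricted strategy evaluation.

Sensitivity is TP/(TP+FN) and specificity TN/(TN+FP), where a true positive
is a patient stratified high-risk whose 5-year endpoint was observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .stratify import DecisionVector, Strategy


class DiagnosticsError(ValueError):
    """Invalid input to a diagnostic-accuracy computation."""


# ---------------------------------------------------------------------------
# confusion counts and proportions


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise DiagnosticsError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with an exact (Clopper–Pearson) confidence interval."""

    estimate: float
    lower: float
    upper: float
    level: float
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.estimate <= self.upper <= 1.0):
            raise DiagnosticsError(
                f"interval ordering violated: {self.lower}, {self.estimate}, {self.upper}"
            )


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: ProportionCI
    specificity: ProportionCI
    ppv: float
    npv: float
    surveillance_fraction: float
    strategy: str
    subgroup: str


def confusion(decisions: DecisionVector | np.ndarray, endpoints: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN from decisions and observed endpoints."""
    high = decisions.high_risk if isinstance(decisions, DecisionVector) else np.asarray(decisions, bool)
    y = np.asarray(endpoints, dtype=bool)
    if len(high) != len(y):
        raise DiagnosticsError(f"length mismatch: {len(high)} decisions vs {len(y)} endpoints")
    return ConfusionCounts(
        tp=int(np.sum(high & y)),
        fp=int(np.sum(high & ~y)),
        fn=int(np.sum(~high & y)),
        tn=int(np.sum(~high & ~y)),
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact two-sided binomial interval via Beta quantiles.

    lower = BetaInv(alpha/2; k, n-k+1), upper = BetaInv(1-alpha/2; k+1, n-k),
    with lower = 0 at k = 0 and upper = 1 at k = n.
    """
    if not 0 < level < 1:
        raise DiagnosticsError(f"confidence level must lie in (0, 1), got {level}")
    if n < 1 or not 0 <= k <= n:
        raise DiagnosticsError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(k / n, lower, upper, level, k, n)


def sens_spec(counts: ConfusionCounts, level: float = 0.95) -> tuple[ProportionCI, ProportionCI]:
    """Sensitivity and specificity with Clopper–Pearson intervals."""
    if counts.tp + counts.fn < 1:
        raise DiagnosticsError("sensitivity undefined: no endpoint-positive patients (tp+fn=0)")
    if counts.tn + counts.fp < 1:
        raise DiagnosticsError("specificity undefined: no endpoint-negative patients (tn+fp=0)")
    sens = clopper_pearson(counts.tp, counts.tp + counts.fn, level)
    spec = clopper_pearson(counts.tn, counts.tn + counts.fp, level)
    return sens, spec


def predictive_values(
    counts: Optional[ConfusionCounts] = None,
    *,
    sensitivity: Optional[float] = None,
    specificity: Optional[float] = None,
    prevalence: Optional[float] = None,
) -> tuple[float, float, float]:
    """PPV, NPV and surveillance fraction.

    Counts mode (``counts`` given): ppv = tp/(tp+fp), npv = tn/(tn+fn),
    surveillance = (tp+fp)/n.

    Scenario mode (``sensitivity``, ``specificity``, ``prevalence`` given):
    Bayes' rule at the stated prevalence pi,

        ppv = s*pi / (s*pi + (1-c)*(1-pi))
        npv = c*(1-pi) / ((1-s)*pi + c*(1-pi))
        surveillance = s*pi + (1-c)*(1-pi)
    """
    if counts is not None:
        if counts.tp + counts.fp < 1:
            raise DiagnosticsError("PPV undefined: no patient stratified high-risk")
        if counts.tn + counts.fn < 1:
            raise DiagnosticsError("NPV undefined: no patient stratified low-risk")
        ppv = counts.tp / (counts.tp + counts.fp)
        npv = counts.tn / (counts.tn + counts.fn)
        return ppv, npv, (counts.tp + counts.fp) / counts.n
    if sensitivity is None or specificity is None or prevalence is None:
        raise DiagnosticsError("scenario mode needs sensitivity, specificity and prevalence")
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise DiagnosticsError("sensitivity and specificity must lie in [0, 1]")
    if not 0.0 < prevalence < 1.0:
        raise DiagnosticsError(f"prevalence must lie in (0, 1), got {prevalence}")
    s, c, pi = sensitivity, specificity, prevalence
    pos = s * pi + (1 - c) * (1 - pi)
    neg = (1 - s) * pi + c * (1 - pi)
    if pos == 0:
        raise DiagnosticsError("PPV undefined: expected high-risk fraction is zero")
    if neg == 0:
        raise DiagnosticsError("NPV undefined: expected low-risk fraction is zero")
    return s * pi / pos, c * (1 - pi) / neg, pos


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve with a DeLong normal-interval AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_lower: float
    auc_upper: float
    level: float


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    statistic: float
    p_raw: float
    p_adjusted: Optional[float] = None


def _check_two_class(endpoints: np.ndarray) -> np.ndarray:
    y = np.asarray(endpoints, dtype=bool)
    if y.all() or not y.any():
        raise DiagnosticsError("need at least one endpoint-positive and one endpoint-negative patient")
    return y


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged) of a 1-D array."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components of one score.

    Returns (auc, v_pos, v_neg): v_pos[i] is the mean Mann–Whitney kernel of
    positive i against all negatives; v_neg[j] symmetrically. Midrank
    formulation, O(N log N).
    """
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    v_pos = (tz[:m] - tx) / n
    v_neg = 1.0 - (tz[m:] - ty) / m
    auc = float(v_pos.mean())
    return auc, v_pos, v_neg


def mann_whitney_auc(scores: np.ndarray, endpoints: np.ndarray) -> float:
    """Tie-corrected Mann–Whitney AUC (ties count one half)."""
    y = _check_two_class(endpoints)
    auc, _, _ = _delong_components(np.asarray(scores, float), y)
    return auc


def empirical_roc(scores: np.ndarray, endpoints: np.ndarray, level: float = 0.95) -> RocCurve:
    """Empirical ROC over every distinct observed score as inclusive threshold.

    The curve includes the degenerate endpoints (0,0) and (1,1); the AUC is
    trapezoidal (equal to the tie-corrected Mann–Whitney statistic) with a
    DeLong-variance normal interval clipped to [0, 1].
    """
    y = _check_two_class(endpoints)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    _, v_pos, v_neg = _delong_components(s, y)
    var = _auc_variance(v_pos, v_neg)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
        auc_lower=float(max(0.0, auc - half)),
        auc_upper=float(min(1.0, auc + half)),
        level=level,
    )


def _auc_variance(v_pos: np.ndarray, v_neg: np.ndarray) -> float:
    m, n = len(v_pos), len(v_neg)
    s10 = v_pos.var(ddof=1) if m > 1 else 0.0
    s01 = v_neg.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_paired(scores_a: np.ndarray, scores_b: np.ndarray, endpoints: np.ndarray) -> DelongResult:
    """DeLong paired test of two AUCs measured on the same patients.

    var(auc_a - auc_b) = (S10_aa + S10_bb - 2 S10_ab)/m + (S01_aa + S01_bb -
    2 S01_ab)/n from the structural-component covariances; the statistic is a
    standard-normal deviate with a two-sided p-value. Identical curves give
    statistic 0 and p = 1; zero variance with unequal AUCs is an error.
    """
    y = _check_two_class(endpoints)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) != len(y):
        raise DiagnosticsError("scores_a, scores_b and endpoints must be aligned")
    auc_a, va_pos, va_neg = _delong_components(a, y)
    auc_b, vb_pos, vb_neg = _delong_components(b, y)
    m, n = len(va_pos), len(va_neg)
    s10 = np.cov(np.vstack([va_pos, vb_pos]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va_neg, vb_neg]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return DelongResult(auc_a, auc_b, 0.0, 1.0)
        raise DiagnosticsError(
            "degenerate DeLong variance with unequal AUCs: scores are not exchangeable"
        )
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, float(z), p)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DiagnosticsError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# strategy evaluation and threshold selection


def evaluate_strategy(
    cohort: Cohort, strategy: Strategy, subgroup: str = "all", level: float = 0.95
) -> DiagnosticSummary:
    """Stratify → confusion → sensitivity/specificity → predictive values,
    restricted to a chromosome-3 availability subgroup."""
    sub = cohort.subgroup(subgroup)
    if sub.n == 0:
        raise DiagnosticsError(f"subgroup {subgroup!r} is empty")
    decisions = strategy.decide(sub)
    counts = confusion(decisions, sub.endpoint)
    sens, spec = sens_spec(counts, level)
    # an empty predicted margin (e.g. a rule enrolling everyone in this
    # subgroup) leaves that predictive value undefined, reported as NaN
    ppv = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else float("nan")
    npv = counts.tn / (counts.tn + counts.fn) if counts.tn + counts.fn else float("nan")
    surv = (counts.tp + counts.fp) / counts.n
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        surveillance_fraction=surv,
        strategy=strategy.label,
        subgroup=subgroup,
    )


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    degenerate: bool  # True when only threshold 0 attains the target


def threshold_for_sensitivity(
    cohort: Cohort, score_field: str, target_sensitivity: float
) -> ThresholdResult:
    """Largest inclusive threshold whose sensitivity meets the target.

    Because sensitivity decreases as the threshold rises, this threshold also
    has the best specificity among all thresholds meeting the target.
    """
    if not 0.0 < target_sensitivity <= 1.0:
        raise DiagnosticsError(f"target sensitivity must lie in (0, 1], got {target_sensitivity}")
    y = _check_two_class(cohort.endpoint)
    s = cohort.df[score_field].to_numpy(dtype=float)
    pos = np.sort(s[y])[::-1]
    m = len(pos)
    k = int(np.ceil(target_sensitivity * m - 1e-12))  # need >= k positives enrolled
    t = float(pos[k - 1])
    degenerate = t <= 0.0
    t = max(t, 0.0)
    counts = confusion(s >= t, y)
    return ThresholdResult(
        threshold=t,
        sensitivity=counts.tp / (counts.tp + counts.fn),
        specificity=counts.tn / (counts.tn + counts.fp),
        degenerate=degenerate,
    )
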