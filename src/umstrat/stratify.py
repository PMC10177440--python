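"""Surveillance stratification strategies.

Each strategy maps a patient to a binary surveillance decision: high risk
(enrol in periodic liver imaging) or low risk (no surveillance). Four kinds
are supported:

- ``score_threshold``: a continuous MAM score against one threshold;
- ``dual_threshold``: separate thresholds for patients with and without a
  chromosome-3 result (full-information score vs degraded score);
- ``stage_threshold``: ordinal stage at or above a cut stage;
- ``monosomy3``: monosomy-3 tumours and untested patients are enrolled,
  disomy-3 patients are not.

All threshold comparisons are inclusive (score >= threshold enrols), matching
the conventional "MAM >= x" notation for these rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import STAGES, Cohort, CohortError, stage_order

STRATEGY_KINDS = ("score_threshold", "dual_threshold", "stage_threshold", "monosomy3")


@dataclass(frozen=True)
class DecisionVector:
    """Per-patient surveillance decisions under one strategy."""

    high_risk: np.ndarray  # bool, aligned with cohort rows
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "high_risk", np.asarray(self.high_risk, dtype=bool))

    def __len__(self) -> int:
        return len(self.high_risk)


@dataclass(frozen=True)
class Strategy:
    """A declarative stratification rule.

    Fields are interpreted according to ``kind``; see module docstring.
    ``score_field`` names the score column for ``score_threshold``;
    ``dual_threshold`` uses ``mam5_full`` for tested patients and
    ``mam5_nochr3`` for untested patients unless overridden.
    """

    kind: str
    label: str
    score_field: Optional[str] = None
    threshold: Optional[float] = None
    threshold_known: Optional[float] = None
    threshold_unknown: Optional[float] = None
    score_field_known: str = "mam5_full"
    score_field_unknown: str = "mam5_nochr3"
    stage_cut: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise CohortError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "score_threshold":
            if self.score_field is None or self.threshold is None:
                raise CohortError("score_threshold strategy needs score_field and threshold")
            _check_threshold(self.threshold)
        elif self.kind == "dual_threshold":
            if self.threshold_known is None or self.threshold_unknown is None:
                raise CohortError("dual_threshold strategy needs threshold_known and threshold_unknown")
            _check_threshold(self.threshold_known)
            _check_threshold(self.threshold_unknown)
        elif self.kind == "stage_threshold":
            if self.stage_cut not in STAGES:
                raise CohortError(f"stage_cut must be one of {STAGES}, got {self.stage_cut!r}")

    def decide(self, cohort: Cohort) -> DecisionVector:
        """Apply the rule to every record of ``cohort``."""
        if self.kind == "score_threshold":
            return stratify_score_threshold(cohort, self.score_field, self.threshold, label=self.label)
        if self.kind == "dual_threshold":
            return stratify_dual_threshold(
                cohort,
                self.score_field_known,
                self.score_field_unknown,
                self.threshold_known,
                self.threshold_unknown,
                label=self.label,
            )
        if self.kind == "stage_threshold":
            return stratify_stage_threshold(cohort, self.stage_cut, label=self.label)
        return stratify_monosomy3(cohort, label=self.label)


def _check_threshold(t: float) -> None:
    if not (0.0 <= t <= 1.0):
        raise CohortError(f"threshold must lie in [0, 1], got {t}")


def _scores(cohort: Cohort, score_field: str) -> np.ndarray:
    if score_field not in cohort.df.columns:
        raise CohortError(f"unknown score field {score_field!r}")
    s = cohort.df[score_field].to_numpy(dtype=float)
    if np.isnan(s).any():
        raise CohortError(f"score field {score_field!r} has missing values")
    return s


def stratify_score_threshold(
    cohort: Cohort, score_field: str, threshold: float, label: str | None = None
) -> DecisionVector:
    """High risk iff score >= threshold (inclusive)."""
    _check_threshold(threshold)
    s = _scores(cohort, score_field)
    return DecisionVector(s >= threshold, label or f"{score_field} >= {threshold}")


def stratify_dual_threshold(
    cohort: Cohort,
    score_field_known: str = "mam5_full",
    score_field_unknown: str = "mam5_nochr3",
    t_known: float = 0.07,
    t_unknown: float = 0.045,
    label: str | None = None,
) -> DecisionVector:
    """Two-threshold decision rule keyed on chromosome-3 availability.

    Tested patients are enrolled iff their full-information score meets
    ``t_known``; untested patients iff their no-chromosome-3 score meets the
    more conservative ``t_unknown``.
    """
    _check_threshold(t_known)
    _check_threshold(t_unknown)
    known = cohort.df["chr3_status"].to_numpy() != "unknown"
    s_known = _scores(cohort, score_field_known)
    s_unknown = _scores(cohort, score_field_unknown)
    high = np.where(known, s_known >= t_known, s_unknown >= t_unknown)
    return DecisionVector(high, label or f"dual {t_known}/{t_unknown}")


def stratify_stage_threshold(cohort: Cohort, stage_cut: str, label: str | None = None) -> DecisionVector:
    """High risk iff stage >= stage_cut in the order I < IIA < ... < IIIC."""
    cut = stage_order(stage_cut)
    ranks = stage_order(cohort.df["stage"])
    if ranks.isna().any():
        bad = cohort.df["stage"][ranks.isna()].iloc[0]
        raise CohortError(f"unknown stage label: {bad!r}")
    return DecisionVector(ranks.to_numpy() >= cut, label or f"stage >= {stage_cut}")


def stratify_monosomy3(cohort: Cohort, label: str | None = None) -> DecisionVector:
    """Monosomy-3 system: monosomy or no chromosome-3 result → surveillance."""
    status = cohort.df["chr3_status"].to_numpy()
    return DecisionVector(status != "disomy", label or "monosomy 3")
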