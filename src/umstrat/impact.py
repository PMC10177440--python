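"""Health-economic impact of surveillance stratification strategies.

Expected confusion counts for a stated population scenario, liver-scan
totals under a fixed schedule (false positives receive ``scans_per_fp``
scans over the horizon, true positives ``scans_per_tp``, negatives none),
and monetary cost at NHS unit costs for non-contrast liver MRI or
ultrasound. Counts are rounded to the nearest whole patient, strategy by
strategy, before any between-strategy difference is taken; costs are
truncated to whole pounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .diagnostics import ConfusionCounts, DiagnosticsError


@dataclass(frozen=True)
class ImpactScenario:
    """Population scenario and scan-schedule assumptions.

    Defaults describe a typical large ocular oncology centre: 200 new
    patients per year, a 28% 5-year endpoint incidence, 10 scans over 5
    years for a false positive, 3 for a true positive, none for negatives,
    and 2020/21 NHS England unit costs of £211.24 (MRI, one area, no
    contrast) and £135.09 (ultrasound, 20+ minutes, no contrast).
    """

    population: int = 200
    incidence: float = 0.28
    scans_per_fp: int = 10
    scans_per_tp: int = 3
    scans_per_negative: int = 0
    unit_cost_mri: float = 211.24
    unit_cost_us: float = 135.09
    horizon_years: int = 5

    def __post_init__(self) -> None:
        if self.population < 1:
            raise DiagnosticsError(f"population must be >= 1, got {self.population}")
        if not 0.0 <= self.incidence <= 1.0:
            raise DiagnosticsError(f"incidence must lie in [0, 1], got {self.incidence}")
        for name in ("scans_per_fp", "scans_per_tp", "scans_per_negative",
                     "unit_cost_mri", "unit_cost_us"):
            if getattr(self, name) < 0:
                raise DiagnosticsError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ImpactReport:
    counts: ConfusionCounts
    scans_total: int
    cost_mri: int
    cost_us: int
    strategy: str
    rounding_repaired: bool = False


@dataclass(frozen=True)
class ImpactDelta:
    """Strategy a relative to comparator b (positive deltas favour a)."""

    fp_avoided: int
    scans_avoided: int
    saving_mri: int
    saving_us: int
    extra_fn: int
    sensitivities_equal: bool


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def expected_counts(
    scenario: ImpactScenario, sensitivity: float, specificity: float
) -> tuple[ConfusionCounts, bool]:
    """Expected TP/FN/FP/TN in the scenario population, each rounded to the
    nearest whole patient.

    total_pos = population*incidence; tp = round(total_pos*sens);
    fn = round(total_pos*(1-sens)); tn = round(total_neg*spec);
    fp = round(total_neg*(1-spec)). If independent rounding breaks the
    population total, the cell whose fraction sat closest to one half is
    adjusted (largest-remainder repair) and the report is flagged.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise DiagnosticsError("sensitivity and specificity must lie in [0, 1]")
    total_pos = scenario.population * scenario.incidence
    total_neg = scenario.population * (1.0 - scenario.incidence)
    raw = [
        total_pos * sensitivity,
        total_pos * (1.0 - sensitivity),
        total_neg * (1.0 - specificity),
        total_neg * specificity,
    ]  # tp, fn, fp, tn
    cells = [_round_half_up(x) for x in raw]
    repaired = False
    diff = scenario.population - sum(cells)
    while diff != 0:
        repaired = True
        # move the cell whose rounding was most ambiguous, in diff's direction
        frac_dist = [abs((x - math.floor(x)) - 0.5) for x in raw]
        idx = min(range(4), key=lambda i: frac_dist[i])
        cells[idx] += 1 if diff > 0 else -1
        raw[idx] = cells[idx]  # do not pick the same cell twice
        diff = scenario.population - sum(cells)
    tp, fn, fp, tn = cells
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn), repaired


def scans_and_costs(
    scenario: ImpactScenario, counts: ConfusionCounts, strategy: str = "",
    rounding_repaired: bool = False,
) -> ImpactReport:
    """Scan total and whole-pound (truncated) cost per imaging modality."""
    scans = (
        scenario.scans_per_fp * counts.fp
        + scenario.scans_per_tp * counts.tp
        + scenario.scans_per_negative * (counts.fn + counts.tn)
    )
    return ImpactReport(
        counts=counts,
        scans_total=int(scans),
        cost_mri=int(math.floor(scans * scenario.unit_cost_mri)),
        cost_us=int(math.floor(scans * scenario.unit_cost_us)),
        strategy=strategy,
        rounding_repaired=rounding_repaired,
    )


def compare_strategies(
    scenario: ImpactScenario,
    summary_a: tuple[float, float],
    summary_b: tuple[float, float],
) -> ImpactDelta:
    """Impact of using strategy a (sens, spec) instead of comparator b.

    Each strategy's expected counts are rounded independently first, then
    differenced. Scans avoided are the false-positive-driven scans,
    fp_avoided * scans_per_fp; when the sensitivities differ the
    true-positive scan load also changes, which this figure deliberately
    excludes (``sensitivities_equal`` is False to flag the extension).
    """
    counts_a, _ = expected_counts(scenario, *summary_a)
    counts_b, _ = expected_counts(scenario, *summary_b)
    fp_avoided = counts_b.fp - counts_a.fp
    scans_avoided = fp_avoided * scenario.scans_per_fp
    return ImpactDelta(
        fp_avoided=fp_avoided,
        scans_avoided=scans_avoided,
        saving_mri=int(math.floor(scans_avoided * scenario.unit_cost_mri)),
        saving_us=int(math.floor(scans_avoided * scenario.unit_cost_us)),
        extra_fn=counts_a.fn - counts_b.fn,
        sensitivities_equal=summary_a[0] == summary_b[0],
    )
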