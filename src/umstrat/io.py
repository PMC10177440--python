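"""Cohort CSV schema, eligibility filtering and run configuration.

The cohort CSV has one row per patient with the columns of
:data:`umstrat.cohort.COLUMNS`. Scores are serialised at full precision
(shortest round-tripping decimal representation), flags as 0/1, and the only
permitted missing value in analysis inputs is the chromosome-3 status token
``"unknown"``. Raw (pre-eligibility) tables may additionally carry optional
``iris_melanoma`` and ``followup_5y`` flags and missing covariates.

Run configuration is a TOML file with ``[generator]`` and ``[impact]``
tables, a ``[[strategies]]`` array and top-level ``seed``, ``level`` and
``out_dir`` keys; unknown keys are rejected.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CHR3_STATUSES, COLUMNS, SCORE_COLUMNS, STAGES, Cohort, CohortError
from .impact import ImpactScenario
from .simulate import GeneratorConfig, config_from_dict, config_to_dict, default_config
from .stratify import Strategy

RAW_OPTIONAL_COLUMNS = ("iris_melanoma", "followup_5y")

_COVARIATE_GROUPS = (
    ("missing age", ("age",)),
    ("missing sex", ("sex",)),
    ("missing tumour dimensions", ("diameter_mm", "height_mm")),
    ("missing ciliary body involvement", ("ciliary_body",)),
    ("missing extraocular extension", ("extraocular",)),
)


# ---------------------------------------------------------------------------
# cohort CSV round trip


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV; floats use their shortest round-trip form."""
    cohort.df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV.

    Raises :class:`CohortError` naming the first offending row (1-based data
    row) and column on any schema violation.
    """
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "sex": str, "chr3_status": str, "stage": str},
        float_precision="round_trip",
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")

    def _offender(mask: pd.Series, column: str, why: str) -> CohortError:
        row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
        return CohortError(f"{path}: row {row}, column {column!r}: {why}")

    for col in COLUMNS:
        if df[col].isna().any():
            raise _offender(df[col].isna(), col, "missing value")
    for col in SCORE_COLUMNS:
        bad = (df[col] < 0) | (df[col] > 1)
        if bad.any():
            raise _offender(bad, col, f"score {df[col][bad].iloc[0]!r} outside [0, 1]")
    bad = ~df["stage"].isin(STAGES)
    if bad.any():
        raise _offender(bad, "stage", f"unknown stage label {df['stage'][bad].iloc[0]!r}")
    bad = ~df["chr3_status"].isin(CHR3_STATUSES)
    if bad.any():
        raise _offender(bad, "chr3_status", f"unknown status {df['chr3_status'][bad].iloc[0]!r}")
    bad = ~df["sex"].isin(("F", "M"))
    if bad.any():
        raise _offender(bad, "sex", f"unknown sex {df['sex'][bad].iloc[0]!r}")
    bad = ~df["endpoint"].isin((0, 1))
    if bad.any():
        raise _offender(bad, "endpoint", "endpoint flag must be 0 or 1")
    return Cohort(df, provenance=str(path))


# ---------------------------------------------------------------------------
# eligibility filter


def eligibility_filter(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Apply the study eligibility rules to a raw patient table.

    Drops records that are iris melanomas, that are missing any of age, sex,
    tumour dimensions, ciliary body involvement or extraocular extension, or
    that lack five years of follow-up without an observed endpoint. Returns
    the eligible table and an exclusion log with exactly one
    (patient_id, reason) entry per dropped record (first matching rule wins).
    """
    raw = raw.reset_index(drop=True)
    reasons: dict[int, str] = {}

    def flag(i: int, reason: str) -> None:
        reasons.setdefault(i, reason)

    if "iris_melanoma" in raw.columns:
        for i in np.flatnonzero(raw["iris_melanoma"].fillna(0).astype(float).to_numpy() == 1):
            flag(int(i), "iris melanoma")
    for reason, cols in _COVARIATE_GROUPS:
        present = [c for c in cols if c in raw.columns]
        if len(present) < len(cols):
            mask = np.ones(len(raw), dtype=bool)  # whole column absent
        else:
            mask = raw[present].isna().any(axis=1).to_numpy()
        for i in np.flatnonzero(mask):
            flag(int(i), reason)
    if "followup_5y" in raw.columns:
        inadequate = raw["followup_5y"].fillna(0).astype(float).to_numpy() == 0
        no_endpoint = raw.get("endpoint", pd.Series(0, index=raw.index)).fillna(0).to_numpy() == 0
        for i in np.flatnonzero(inadequate & no_endpoint):
            flag(int(i), "less than 5 years of follow-up without observed endpoint")

    excluded = sorted(reasons)
    log = [(str(raw["patient_id"].iloc[i]), reasons[i]) for i in excluded]
    eligible = raw.drop(index=excluded).reset_index(drop=True)
    eligible = eligible.drop(columns=[c for c in RAW_OPTIONAL_COLUMNS if c in eligible.columns])
    return eligible, log


# ---------------------------------------------------------------------------
# run configuration (TOML)


def default_strategies() -> list[Strategy]:
    """The four stratification systems at their headline thresholds."""
    return [
        Strategy(kind="score_threshold", label="MAM full >= 0.05",
                 score_field="mam5_full", threshold=0.05),
        Strategy(kind="dual_threshold", label="MAM dual 0.07/0.045",
                 threshold_known=0.07, threshold_unknown=0.045),
        Strategy(kind="stage_threshold", label="stage >= IIA", stage_cut="IIA"),
        Strategy(kind="monosomy3", label="monosomy 3"),
    ]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=default_config)
    strategies: list[Strategy] = field(default_factory=default_strategies)
    scenario: ImpactScenario = field(default_factory=ImpactScenario)
    # (label, sensitivity, specificity) rows for the impact table, plus
    # (strategy label, comparator label) pairs for the delta report.
    impact_rates: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("LUMPOIII dual", 0.95, 0.51), ("AJCC >= IIA", 0.95, 0.38)]
    )
    impact_comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("LUMPOIII dual", "AJCC >= IIA")]
    )
    seed: int = 0
    level: float = 0.95
    out_dir: str = "umstrat_out"


_STRATEGY_KEYS = {
    "kind", "label", "score_field", "threshold", "threshold_known",
    "threshold_unknown", "score_field_known", "score_field_unknown", "stage_cut",
}
_TOP_KEYS = {"generator", "strategies", "impact", "seed", "level", "out_dir"}
_IMPACT_KEYS = {
    "population", "incidence", "scans_per_fp", "scans_per_tp", "scans_per_negative",
    "unit_cost_mri", "unit_cost_us", "horizon_years", "rates", "comparisons",
}


def read_run_config(path: str | Path) -> RunConfig:
    """Parse a TOML run configuration, rejecting unknown keys."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise CohortError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig()
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "level" in data:
        cfg.level = float(data["level"])
    if "out_dir" in data:
        cfg.out_dir = str(data["out_dir"])
    gen = dict(data.get("generator", {}))
    gen.setdefault("seed", cfg.seed)
    cfg.generator = config_from_dict(gen)
    if "strategies" in data:
        cfg.strategies = []
        for entry in data["strategies"]:
            unknown = set(entry) - _STRATEGY_KEYS
            if unknown:
                raise CohortError(f"{path}: unknown strategy keys {sorted(unknown)}")
            cfg.strategies.append(Strategy(**entry))
    if "impact" in data:
        imp = dict(data["impact"])
        unknown = set(imp) - _IMPACT_KEYS
        if unknown:
            raise CohortError(f"{path}: unknown impact keys {sorted(unknown)}")
        rates = imp.pop("rates", None)
        comparisons = imp.pop("comparisons", None)
        cfg.scenario = ImpactScenario(**imp)
        if rates is not None:
            cfg.impact_rates = [(str(r[0]), float(r[1]), float(r[2])) for r in rates]
        if comparisons is not None:
            cfg.impact_comparisons = [(str(a), str(b)) for a, b in comparisons]
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def write_generator_config(config: GeneratorConfig, path: str | Path) -> None:
    """Write a generator configuration as the ``[generator]`` table of a
    TOML file readable by :func:`read_run_config`."""
    d = config_to_dict(config)
    lines = ["[generator]"]
    # scalars first: a bare key after a [generator.x] header would nest in x
    for key, val in d.items():
        if not isinstance(val, dict):
            lines.append(f"{key} = {_toml_value(val)}")
    for key, val in d.items():
        if isinstance(val, dict):  # mixtures
            lines.append(f"[generator.{key}]")
            for k2, v2 in val.items():
                lines.append(f"{k2} = {_toml_value(v2)}")
    Path(path).write_text("\n".join(lines) + "\n")
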