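"""End-to-end analysis pipeline.

Generates (or loads) a cohort, evaluates every configured strategy on the
whole cohort and on the chromosome-3 known/unknown subgroups, runs ROC/AUC
analysis with DeLong paired comparisons between the score channels (Holm
adjustment across the executed comparison family), computes the impact table
and strategy-vs-strategy deltas, and writes the bundle as CSV files plus a
plain-text run log.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .cohort import SCORE_COLUMNS, SUBGROUPS, Cohort
from .diagnostics import delong_paired, empirical_roc, evaluate_strategy, holm_adjust
from .impact import compare_strategies, expected_counts, scans_and_costs
from .io import RunConfig, read_cohort, write_cohort, write_generator_config
from .simulate import config_to_dict, generate_cohort


def _percent(x: float) -> int | str:
    """Nearest whole percent, matching report-table presentation."""
    if x != x:  # NaN: undefined cell (e.g. NPV with nobody low-risk)
        return ""
    return int(round(100.0 * x))


def summary_table(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    """One row per (strategy x subgroup) in report-table layout."""
    rows = []
    for strategy in config.strategies:
        for subgroup in SUBGROUPS:
            sub = cohort.subgroup(subgroup)
            if sub.n == 0 or len(set(sub.endpoint)) < 2:
                continue
            s = evaluate_strategy(cohort, strategy, subgroup, level=config.level)
            rows.append(
                {
                    "system": s.strategy,
                    "subgroup": s.subgroup,
                    "n": sub.n,
                    "sensitivity_pct": _percent(s.sensitivity.estimate),
                    "sensitivity_ci": f"{_percent(s.sensitivity.lower)}-{_percent(s.sensitivity.upper)}",
                    "specificity_pct": _percent(s.specificity.estimate),
                    "specificity_ci": f"{_percent(s.specificity.lower)}-{_percent(s.specificity.upper)}",
                    "ppv_pct": _percent(s.ppv),
                    "npv_pct": _percent(s.npv),
                    "surveillance_pct": _percent(s.surveillance_fraction),
                }
            )
    return pd.DataFrame(rows)


def roc_tables(cohort: Cohort, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROC operating points per score channel, and the AUC/DeLong report.

    The DeLong family is every pairwise comparison between the three score
    channels on the full cohort; Holm adjustment spans exactly that family.
    """
    points = []
    auc_rows = []
    for field in SCORE_COLUMNS:
        roc = empirical_roc(
            cohort.df[field].to_numpy(), cohort.endpoint, level=config.level
        )
        points.append(
            pd.DataFrame(
                {
                    "score_field": field,
                    "threshold": roc.thresholds,
                    "fpr": roc.fpr,
                    "tpr": roc.tpr,
                }
            )
        )
        auc_rows.append(
            {"comparison": f"auc:{field}", "auc_a": roc.auc, "auc_b": "",
             "auc_ci": f"{roc.auc_lower:.3f}-{roc.auc_upper:.3f}",
             "statistic": "", "p_raw": "", "p_holm": ""}
        )
    results = []
    pairs = list(itertools.combinations(SCORE_COLUMNS, 2))
    for a, b in pairs:
        res = delong_paired(
            cohort.df[a].to_numpy(), cohort.df[b].to_numpy(), cohort.endpoint
        )
        results.append((a, b, res))
    adjusted = holm_adjust([r.p_raw for _, _, r in results])
    for (a, b, res), p_adj in zip(results, adjusted):
        auc_rows.append(
            {"comparison": f"delong:{a} vs {b}", "auc_a": res.auc_a, "auc_b": res.auc_b,
             "auc_ci": "", "statistic": res.statistic, "p_raw": res.p_raw, "p_holm": p_adj}
        )
    return pd.concat(points, ignore_index=True), pd.DataFrame(auc_rows)


def impact_tables(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impact table (one row per configured rate pair) and delta report."""
    reports = {}
    rows = []
    for label, sens, spec in config.impact_rates:
        counts, repaired = expected_counts(config.scenario, sens, spec)
        rep = scans_and_costs(config.scenario, counts, strategy=label, rounding_repaired=repaired)
        reports[label] = (sens, spec)
        rows.append(
            {
                "system": label,
                "sensitivity_pct": _percent(sens),
                "specificity_pct": _percent(spec),
                "true_positives": counts.tp,
                "false_negatives": counts.fn,
                "false_positives": counts.fp,
                "true_negatives": counts.tn,
                "total": counts.n,
                "scans_total": rep.scans_total,
                "cost_mri_gbp": rep.cost_mri,
                "cost_us_gbp": rep.cost_us,
                "rounding_repaired": repaired,
            }
        )
    delta_rows = []
    for label_a, label_b in config.impact_comparisons:
        if label_a not in reports or label_b not in reports:
            raise KeyError(f"impact comparison references unknown strategy: {label_a!r} vs {label_b!r}")
        d = compare_strategies(config.scenario, reports[label_a], reports[label_b])
        delta_rows.append(
            {
                "strategy": label_a,
                "comparator": label_b,
                "fp_avoided": d.fp_avoided,
                "scans_avoided": d.scans_avoided,
                "saving_mri_gbp": d.saving_mri,
                "saving_us_gbp": d.saving_us,
                "extra_fn": d.extra_fn,
                "sensitivities_equal": d.sensitivities_equal,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(delta_rows)


def _config_hash(config: RunConfig) -> str:
    text = repr(
        (
            sorted(config_to_dict(config.generator).items(), key=lambda kv: kv[0]),
            [asdict(s) for s in config.strategies],
            asdict(config.scenario),
            config.impact_rates,
            config.impact_comparisons,
            config.seed,
            config.level,
        )
    )
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig, cohort_path: str | Path | None = None, timestamp: bool = True
) -> dict[str, Path]:
    """Run the full analysis and write the output bundle.

    Parameters
    ----------
    config : RunConfig
    cohort_path : optional path
        Read the cohort from this CSV instead of generating one.
    timestamp : bool
        Include wall-clock timestamps in the run log (disable for
        byte-identical reruns).

    Returns
    -------
    dict mapping bundle member names to written paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg: str) -> None:
        if timestamp:
            msg = f"{datetime.now(timezone.utc).isoformat(timespec='seconds')} {msg}"
        log_lines.append(msg)

    log(f"run seed={config.seed} config_hash={_config_hash(config)}")
    paths: dict[str, Path] = {}

    if cohort_path is None:
        cohort = generate_cohort(config.generator)
        log(f"generated cohort n={cohort.n}")
    else:
        cohort = read_cohort(cohort_path)
        log(f"read cohort n={cohort.n} from {cohort_path}")
    paths["cohort"] = out / "cohort.csv"
    write_cohort(cohort, paths["cohort"])
    paths["generator_config"] = out / "generator_config.toml"
    write_generator_config(config.generator, paths["generator_config"])

    summary = summary_table(cohort, config)
    paths["summary"] = out / "strategy_summary.csv"
    summary.to_csv(paths["summary"], index=False)
    log(f"evaluated {len(config.strategies)} strategies on {len(summary)} (strategy, subgroup) cells")

    roc_points, auc_report = roc_tables(cohort, config)
    paths["roc_points"] = out / "roc_points.csv"
    roc_points.to_csv(paths["roc_points"], index=False)
    paths["auc_report"] = out / "auc_delong.csv"
    auc_report.to_csv(paths["auc_report"], index=False)
    n_cmp = int(auc_report["comparison"].str.startswith("delong:").sum())
    log(f"Holm family: {n_cmp} DeLong comparisons "
        f"({', '.join(auc_report.loc[auc_report['comparison'].str.startswith('delong:'), 'comparison'])})")

    impact, deltas = impact_tables(config)
    paths["impact"] = out / "impact.csv"
    impact.to_csv(paths["impact"], index=False)
    paths["impact_deltas"] = out / "impact_deltas.csv"
    deltas.to_csv(paths["impact_deltas"], index=False)
    log("impact tables written")

    paths["log"] = out / "run.log"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
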