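"""End-to-end orchestration: simulate -> clean -> decompose -> phenology ->
statistics, plus summary-table generation and the published-table arithmetic
checks.

The reporting layer aggregates the per-tree-year metrics table to treatment
x year means ("Table-1 style"), runs the trimmed-mean split-plot ANOVA per
metric ("Table-2 style") and the Spearman correlation matrix among metrics
("Table-3 style").  Yearly cells and the Means column are simple means over
the valid tree-seasons available in that cell; exclusion accounting (how
many of the possible tree-seasons were characterized, and why the others
were not) is part of the report bundle.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phenology, preprocess, robust_stats, synthetic, zero_growth
from .phenology import SeasonParams
from .preprocess import CleaningParams
from .synthetic import HeatedEffects, SimulationConfig

__all__ = [
    "RunConfig",
    "run_pipeline",
    "metrics_from_trees",
    "treatment_year_table",
    "treatment_contrasts",
    "anova_table",
    "verify_table_arithmetic",
    "load_table1_fixture",
]

log = logging.getLogger(__name__)

METRIC_COLS = ("onset_doy", "cessation_doy", "duration_days",
               "total_growth_um", "rate_um_per_day")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-experiment pipeline run."""

    seed: int = 0
    n_control: int = 6
    n_heated: int = 6
    years: int = 12
    base: SimulationConfig = field(default_factory=SimulationConfig)
    heated_effects: HeatedEffects = field(default_factory=HeatedEffects)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    season: SeasonParams = field(default_factory=SeasonParams)
    trim: float = 0.2
    out_dir: Path | None = None


def metrics_from_trees(trees: list[synthetic.SyntheticTree],
                       cleaning: CleaningParams = CleaningParams(),
                       season: SeasonParams = SeasonParams(),
                       do_clean: bool = True) -> pd.DataFrame:
    """Clean, decompose and extract season metrics for simulated trees."""
    treatments = {t.radius_series.series_id: t.config.treatment for t in trees}
    decomps = []
    for t in trees:
        s = t.radius_series
        if do_clean:
            s = preprocess.clean(s, t.temperature_series, cleaning)
        decomps.append(zero_growth.decompose(s))
    return phenology.metrics_table(decomps, season, treatments=treatments)


def treatment_year_table(metrics: pd.DataFrame, metric: str,
                         q: float = 0.05) -> pd.DataFrame:
    """Treatment x year means of one metric at tolerance q, with an Overall
    row and a Means column (simple means over available tree-seasons)."""
    sub = metrics[(metrics["q"] == q) & metrics["valid"]]
    table = sub.pivot_table(index="treatment", columns="year", values=metric,
                            aggfunc="mean")
    overall = sub.groupby("year")[metric].mean()
    table.loc["overall"] = overall
    table["mean"] = table.mean(axis=1)
    return table


def treatment_contrasts(metrics: pd.DataFrame, q: float = 0.05) -> dict[str, float]:
    """Headline heated-vs-control contrasts from the Means column."""
    out = {}
    for metric, key, kind in (
        ("rate_um_per_day", "rate_contrast_pct", "pct"),
        ("total_growth_um", "total_growth_contrast_pct", "pct"),
        ("duration_days", "duration_contrast_days", "diff"),
        ("cessation_doy", "cessation_shift_days", "diff"),
        ("onset_doy", "onset_shift_days", "diff"),
    ):
        table = treatment_year_table(metrics, metric, q)
        heated, control = table.loc["heated", "mean"], table.loc["control", "mean"]
        if kind == "pct":
            out[key] = 100.0 * (heated - control) / control
        else:
            out[key] = heated - control
    return out


def anova_table(metrics: pd.DataFrame, trim: float = 0.2) -> pd.DataFrame:
    """Trimmed-mean split-plot ANOVA for every metric x tolerance."""
    rows = []
    for metric in METRIC_COLS:
        for q in sorted(metrics["q"].unique()):
            sub = metrics[(metrics["q"] == q) & metrics["valid"]]
            sub = sub.rename(columns={"series_id": "tree_id"})
            try:
                res = robust_stats.bw_trimmed_anova(sub, metric, trim=trim)
            except ValueError as err:
                log.warning("ANOVA skipped for %s q=%.2f: %s", metric, q, err)
                continue
            for eff, r in res.items():
                rows.append({"metric": metric, "q": q, "effect": eff,
                             "statistic": r.statistic, "df1": r.df1,
                             "df2": r.df2, "p_value": r.p_value,
                             "stars": r.stars})
    return pd.DataFrame(rows)


def correlation_report(metrics: pd.DataFrame,
                       qs: tuple[float, ...] = (0.20, 0.10, 0.05)
                       ) -> robust_stats.CorrelationMatrix:
    """Spearman matrix ordered: onset (5%), cessation at each q (descending,
    i.e. 80/90/95% completion), duration at each q, total growth, rate."""
    valid = metrics[metrics["valid"]]
    wide = {}
    base = valid[valid["q"] == 0.05].set_index(["series_id", "year"])
    wide["onset_5"] = base["onset_doy"]
    for q in qs:
        sub = valid[valid["q"] == q].set_index(["series_id", "year"])
        pct = int(round(100 * (1 - q)))
        wide[f"cessation_{pct}"] = sub["cessation_doy"]
    for q in qs:
        sub = valid[valid["q"] == q].set_index(["series_id", "year"])
        pct = int(round(100 * (1 - q)))
        wide[f"duration_{pct}"] = sub["duration_days"]
    wide["total"] = base["total_growth_um"]
    wide["rate"] = base["rate_um_per_day"]
    panel = pd.DataFrame(wide).reset_index(drop=True)
    return robust_stats.correlation_table(panel, list(panel.columns))


def exclusion_accounting(metrics: pd.DataFrame, q: float = 0.05) -> pd.Series:
    """How many tree-seasons were characterized, and why the rest were not."""
    sub = metrics[metrics["q"] == q]
    counts = sub["reason"].replace("", "valid").value_counts()
    counts.index.name = "status"
    return counts


def run_pipeline(config: RunConfig) -> dict:
    """Full deterministic pipeline on a synthetic experiment.

    Returns a bundle with the ground truth, metrics table, Table-style
    reports, contrasts, ANOVA, correlations and exclusion accounting; writes
    CSV outputs when ``config.out_dir`` is set.
    """
    trees = synthetic.simulate_experiment(
        config.n_control, config.n_heated, config.years, base=config.base,
        heated_effects=config.heated_effects, seed=config.seed)
    truth = synthetic.experiment_truth_table(trees)
    metrics = metrics_from_trees(trees, config.cleaning, config.season)
    tables = {m: treatment_year_table(metrics, m) for m in METRIC_COLS}
    bundle = {
        "truth": truth,
        "metrics": metrics,
        "tables": tables,
        "contrasts": treatment_contrasts(metrics),
        "anova": anova_table(metrics, config.trim),
        "correlations": correlation_report(
            metrics, tuple(sorted(config.season.tol_seas, reverse=True))),
        "exclusions": exclusion_accounting(metrics),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth.to_csv(out / "ground_truth.csv", index=False)
        metrics.to_csv(out / "season_metrics.csv", index=False)
        bundle["anova"].to_csv(out / "anova.csv", index=False)
        bundle["correlations"].rho.to_csv(out / "correlations_rho.csv")
        for m, tab in tables.items():
            tab.to_csv(out / f"table_{m}.csv")
        bundle["exclusions"].to_csv(out / "exclusions.csv")
    return bundle


# ---------------------------------------------------------------------------
# Published-table arithmetic


def load_table1_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """The shipped transcription of the published treatment x year means."""
    if path is None:
        ref = importlib.resources.files("dendroseason") / "data" / "table1_means.csv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def verify_table_arithmetic(path: str | Path | None = None) -> dict[str, float]:
    """Recompute the headline quantities from the published means table.

    Overall onset/cessation/duration are means of the 12 yearly overall
    values; the treatment contrasts use the published Means column (which,
    because of unbalanced tree counts, is not the mean of the yearly means).
    """
    fx = load_table1_fixture(path)

    def cell(metric, group, year):
        sel = fx[(fx["metric"] == metric) & (fx["group"] == group)
                 & (fx["year"] == year)]
        if len(sel) != 1:
            raise ValueError(f"fixture lookup failed: {metric}/{group}/{year}")
        return float(sel["value"].iloc[0])

    def yearly_overall(metric):
        sel = fx[(fx["metric"] == metric) & (fx["group"] == "overall")
                 & (fx["year"] != "mean")]
        return sel["value"].astype(float).to_numpy()

    onset_mean = float(np.mean(yearly_overall("onset_q05")))
    duration_mean = float(np.mean(yearly_overall("duration_q05")))
    cessation_mean = float(np.mean(yearly_overall("cessation_q05")))
    rate_c, rate_h = cell("rate", "control", "mean"), cell("rate", "heated", "mean")
    tot_c, tot_h = (cell("total_growth", "control", "mean"),
                    cell("total_growth", "heated", "mean"))
    dur_c, dur_h = (cell("duration_q05", "control", "mean"),
                    cell("duration_q05", "heated", "mean"))
    cess80 = cell("cessation_q20", "overall", "mean")
    return {
        "overall_onset_doy": onset_mean,
        "overall_cessation_doy": cessation_mean,
        "overall_duration_days": duration_mean,
        "rate_contrast_pct": 100.0 * (rate_h - rate_c) / rate_c,
        "total_growth_contrast_pct": 100.0 * (tot_h - tot_c) / tot_c,
        "duration_contrast_days": dur_c - dur_h,
        "onset_to_80pct_days": cess80 - onset_mean,
    }
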