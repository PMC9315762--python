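import numpy as np
import pandas as pd
import pytest

from dendroseason import EffectSizes, SimulationConfig, simulate_tree
from dendroseason.phenology import SeasonParams, season_metrics
from dendroseason.preprocess import clean
from dendroseason.zero_growth import decompose

N_RECOVERY_SEEDS = 50


@pytest.fixture(scope="session")
def recovery_study() -> pd.DataFrame:
    """Full-chain parameter recovery over seeded synthetic trees.

    Each tree runs simulate -> clean -> decompose -> season metrics; errors
    are extraction minus realized ground truth.  Shared by the recovery and
    tolerance-sensitivity tests.
    """
    rows = []
    params = SeasonParams()
    for seed in range(N_RECOVERY_SEEDS):
        tree = simulate_tree(SimulationConfig(seed=seed, n_years=3))
        cleaned = clean(tree.radius_series, tree.temperature_series)
        z = decompose(cleaned)
        for _, tr in tree.truth.iterrows():
            sm = season_metrics(z, int(tr["year"]), params)
            for _, r in sm.iterrows():
                if not r["valid"]:
                    continue
                rows.append({
                    "seed": seed, "year": int(tr["year"]), "q": r["q"],
                    "onset_doy": r["onset_doy"], "cessation_doy": r["cessation_doy"],
                    "onset_err": r["onset_doy"] - tr["onset_true"],
                    "cessation_err": r["cessation_doy"] - tr["cessation_true"],
                    "growth_err_pct": 100.0 * (r["annual_growth_um"] - tr["growth_true_um"])
                    / tr["growth_true_um"],
                    "duration_days": r["duration_days"],
                    "total_growth_um": r["total_growth_um"],
                    "rate_um_per_day": r["rate_um_per_day"],
                })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_effects() -> EffectSizes:
    """Low tree/residual variability (year effects kept) for clean recovery
    of the configured treatment contrasts."""
    return EffectSizes(tree_onset_sd=1.0, tree_cessation_sd=1.5,
                       tree_log_growth_sd=0.03, resid_onset_sd=1.0,
                       resid_cessation_sd=2.0, resid_log_growth_sd=0.025)


@pytest.fixture()
def daily_index():
    def make(year: int, n_days: int | None = None):
        start = pd.Timestamp(year=year, month=1, day=1)
        n = n_days or (366 if start.is_leap_year else 365)
        return pd.date_range(start, periods=n, freq="D")
    return make
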