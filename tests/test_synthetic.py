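"""Simulator contracts: degenerate limits, determinism, signal structure."""

import numpy as np
import pandas as pd
import pytest

from dendroseason import (
    HeatedEffects,
    SimulationConfig,
    simulate_experiment,
    simulate_metrics_panel,
    simulate_tree,
)
from dendroseason.synthetic import experiment_truth_table


def _pure_growth(seed=1, **kw):
    kw.setdefault("noise_sd_um", 0.0)
    kw.setdefault("diurnal_amplitude_um", 0.0)
    kw.setdefault("winter_shrinkage_um", 0.0)
    return SimulationConfig(seed=seed, **kw)


class TestSimulateTree:
    def test_pure_growth_is_monotone_with_exact_annual_increment(self):
        tree = simulate_tree(_pure_growth(n_years=2, annual_growth_um=1000.0))
        v = tree.radius_series.values.to_numpy()
        assert np.all(np.diff(v) >= -1e-9)
        assert v[-1] - v[0] == pytest.approx(2000.0, abs=0.01)

    def test_seeded_runs_are_bit_identical(self):
        cfg = SimulationConfig(seed=42, n_years=2)
        a = simulate_tree(cfg).radius_series.values.to_numpy()
        b = simulate_tree(cfg).radius_series.values.to_numpy()
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate_tree(SimulationConfig(seed=1, n_years=2)).radius_series
        b = simulate_tree(SimulationConfig(seed=2, n_years=2)).radius_series
        assert not np.array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_diurnal_cycle_has_daily_period_and_zero_daily_mean(self):
        cfg = _pure_growth(n_years=1, annual_growth_um=0.0,
                           diurnal_amplitude_um=40.0, baseline_um=5000.0)
        tree = simulate_tree(cfg)
        fr = tree.radius_series.frame
        v = fr["value"].to_numpy()
        # period exactly steps_per_day
        assert np.allclose(v[: 96 * 30], v[96: 96 * 31])
        daily = fr["value"].groupby(fr.index.normalize()).mean()
        assert np.allclose(daily.to_numpy(), 5000.0, atol=1e-9)
        assert np.ptp(v) == pytest.approx(40.0, rel=1e-3)

    def test_winter_shrinkage_cycle_is_net_zero(self):
        base = dict(n_years=2, annual_growth_um=800.0)
        with_w = simulate_tree(_pure_growth(winter_shrinkage_um=600.0, **base))
        without = simulate_tree(_pure_growth(**base))
        a, b = with_w.radius_series.frame, without.radius_series.frame
        summer = pd.Timestamp(2011, 7, 1)
        assert a.loc[summer, "value"] == pytest.approx(b.loc[summer, "value"], abs=1e-6)
        winter = pd.Timestamp(2011, 2, 1)
        assert b.loc[winter, "value"] - a.loc[winter, "value"] == pytest.approx(600.0, abs=1e-6)

    def test_series_length_minus_gaps(self):
        cfg = SimulationConfig(seed=0, n_years=2, gap_spec=((100, 5), (2000, 50)))
        tree = simulate_tree(cfg)
        assert len(tree.radius_series) == (365 + 365) * 96 - 55
        assert len(tree.temperature_series) == len(tree.radius_series)

    def test_jump_spec_offsets_subsequent_values(self):
        cfg = _pure_growth(n_years=1, annual_growth_um=100.0,
                           jump_spec=((5000, 250.0),))
        ref = simulate_tree(_pure_growth(n_years=1, annual_growth_um=100.0))
        tree = simulate_tree(cfg)
        d = tree.radius_series.values.to_numpy() - ref.radius_series.values.to_numpy()
        assert np.allclose(d[:5000], 0.0) and np.allclose(d[5000:], 250.0)

    def test_truth_realized_equals_configured_without_shrinkage(self):
        cfg = _pure_growth(n_years=2, onset_doy_true=152, cessation_doy_true=244)
        truth = simulate_tree(cfg).truth.iloc[0]
        assert truth["onset_true"] == 152
        assert truth["cessation_true"] == 244
        assert truth["growth_true_um"] == pytest.approx(1160.0, abs=0.01)

    def test_heated_temperature_offset_in_frost_free_season(self):
        c = simulate_tree(SimulationConfig(seed=5, n_years=1, temp_noise_sd_c=0.0))
        h = simulate_tree(SimulationConfig(seed=5, n_years=1, temp_noise_sd_c=0.0,
                                           treatment="heated"))
        d = h.temperature_series.temps - c.temperature_series.temps
        july = d[d.index.month == 7]
        jan = d[d.index.month == 1]
        assert np.allclose(july.to_numpy(), 4.0)
        assert np.allclose(jan.to_numpy(), 0.0)

    def test_dead_tree_has_no_valid_season(self):
        cfg = SimulationConfig(seed=9, n_years=3, dead_from_year=2)
        truth = simulate_tree(cfg).truth
        assert not truth["valid_true"].any()

    @pytest.mark.parametrize("bad", [
        dict(onset_doy_true=250, cessation_doy_true=200),
        dict(annual_growth_um=-5.0),
        dict(noise_sd_um=-1.0),
        dict(annual_growth_um=float("nan")),
        dict(rehydration_start_doy=100, rehydration_end_doy=150),  # overlaps onset
        dict(treatment="warmed"),
    ])
    def test_invalid_configs_raise(self, bad):
        with pytest.raises(ValueError):
            simulate_tree(SimulationConfig(seed=0, n_years=2, **bad))


class TestExperiment:
    def test_truth_table_bookkeeping(self):
        trees = simulate_experiment(2, 2, 3, seed=0)
        truth = experiment_truth_table(trees)
        assert len(truth) == 4 * 3
        assert set(truth["treatment"]) == {"control", "heated"}
        # one extra burn-in calendar year precedes the measurable seasons
        assert all(len(t.radius_series.frame.index.year.unique()) == 4 for t in trees)

    def test_heated_configured_contrast_signs(self, small_effects):
        trees = simulate_experiment(4, 4, 6, seed=3, effects=small_effects)
        truth = experiment_truth_table(trees)
        g = truth.groupby("treatment")[["cessation_cfg", "growth_cfg_um"]].mean()
        assert g.loc["heated", "cessation_cfg"] < g.loc["control", "cessation_cfg"]
        assert g.loc["heated", "growth_cfg_um"] > g.loc["control", "growth_cfg_um"]

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            simulate_experiment(0, 6, 3)

    def test_metrics_panel_shape_and_identities(self):
        panel = simulate_metrics_panel(3, 4, 5, seed=1)
        assert len(panel) == 7 * 5
        assert np.allclose(panel["duration"],
                           panel["cessation"] - panel["onset"])
        assert np.allclose(panel["rate"] * panel["duration"], panel["total"])

    def test_null_panel_groups_exchangeable(self):
        null = HeatedEffects(cessation_shift_days=0.0, rate_multiplier=1.0)
        panels = [simulate_metrics_panel(6, 6, 12, heated_effects=null, seed=s)
                  for s in range(40)]
        diffs = [p.groupby("treatment")["rate"].mean().diff().iloc[-1] for p in panels]
        # heated-minus-control mean rate centred on zero under the null
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs))
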