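"""Robust statistics: trimmed means, split-plot trimmed ANOVA, Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats as st_sp

from dendroseason.robust_stats import (
    bw_trimmed_anova,
    correlation_table,
    p_stars,
    spearman,
    trimmed_mean,
)


def _panel(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """groups: treatment -> (subjects x years) matrix."""
    rows = []
    for g, mat in groups.items():
        mat = np.atleast_2d(mat)
        for i, subj in enumerate(mat):
            for k, v in enumerate(subj):
                rows.append({"tree_id": f"{g}{i}", "treatment": g,
                             "year": 2000 + k, "m": v})
    return pd.DataFrame(rows)


class TestTrimmedMean:
    def test_one_to_ten_trim_20pct(self):
        assert trimmed_mean(np.arange(1, 11), 0.2) == pytest.approx(5.5)

    def test_trim_zero_is_arithmetic_mean(self):
        x = [3.0, 1.0, 7.0]
        assert trimmed_mean(x, 0.0) == pytest.approx(np.mean(x))

    def test_insensitive_to_extreme_outlier(self):
        a = trimmed_mean(list(range(1, 10)) + [1000], 0.2)
        b = trimmed_mean(list(range(1, 10)) + [10], 0.2)
        assert a == pytest.approx(b)

    def test_over_trimming_raises(self):
        with pytest.raises(ValueError, match="over-trimming"):
            trimmed_mean([1.0, 2.0], 0.5)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=40),
           st.floats(0, 0.24))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_location_equivariant_and_bounded(self, x, trim):
        tm = trimmed_mean(x, trim)
        assert min(x) - 1e-9 <= tm <= max(x) + 1e-9
        shifted = trimmed_mean(np.asarray(x) + 100.0, trim)
        assert shifted == pytest.approx(tm + 100.0, abs=1e-6 * max(1, abs(tm)))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(-2, 2, 20)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_constant_input_flagged_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)

    @pytest.mark.parametrize("seed", range(6))
    def test_ties_match_brute_force_average_ranks(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 7).astype(float)
        y = rng.integers(0, 4, 7).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return

        def brute_ranks(v):
            # average rank: mean 1-based position of each value when sorted
            return np.array([
                np.mean([j + 1 for j, u in enumerate(sorted(v)) if u == val])
                for val in v])

        rho, _ = spearman(x, y)
        rx, ry = brute_ranks(x), brute_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(-100, 100).filter(lambda v: v == 0 or abs(v) > 1e-3),
                    min_size=6, max_size=30, unique=True))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, x):
        x = np.asarray(x)
        tx = np.exp(x / 100.0)  # strictly increasing map
        # rounding must not collapse near-equal inputs into ties
        assume(len(np.unique(tx)) == len(tx))
        y = np.sin(x)  # arbitrary paired variable
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(tx, y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestBwTrimmedAnova:
    def test_identical_observations_give_zero_stat_unit_p(self):
        panel = _panel({"c": np.full((4, 3), 7.0), "h": np.full((4, 3), 7.0)})
        res = bw_trimmed_anova(panel, "m")
        for eff in ("treatment", "year", "interaction"):
            assert res[eff].statistic == 0.0
            assert res[eff].p_value == 1.0

    def test_reduces_to_welch_t_when_untrimmed_single_year(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 9), rng.normal(0.8, 2, 12)
        res = bw_trimmed_anova(_panel({"c": x[:, None], "h": y[:, None]}),
                               "m", trim=0.0)["treatment"]
        t, p = st_sp.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(t**2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_reduces_to_yuen_trimmed_t_single_year(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 2, 13)
        res = bw_trimmed_anova(_panel({"c": x[:, None], "h": y[:, None]}),
                               "m", trim=0.2)["treatment"]
        t, p = st_sp.ttest_ind(x, y, equal_var=False, trim=0.2)
        assert res.statistic == pytest.approx(t**2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_statistic_invariant_under_location_shift(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, (5, 4)), rng.normal(0.3, 1, (6, 4))
        r1 = bw_trimmed_anova(_panel({"c": a, "h": b}), "m")
        r2 = bw_trimmed_anova(_panel({"c": a + 50, "h": b + 50}), "m")
        for eff in r1:
            assert r1[eff].statistic == pytest.approx(r2[eff].statistic, rel=1e-9)

    def test_between_effect_tracks_classical_split_plot_when_untrimmed(self):
        # large balanced panel, homoscedastic errors: the Johansen-type
        # between-groups test approaches the classical split-plot F
        rng = np.random.default_rng(7)
        n, k = 40, 3
        subj = rng.normal(0, 1.0, (2, n, 1))
        eps = rng.normal(0, 1.0, (2, n, k))
        data = {g: 0.5 * (gi) + subj[gi] + eps[gi] for gi, g in enumerate("ch")}
        res = bw_trimmed_anova(_panel(data), "m", trim=0.0)["treatment"]
        # classical between-subjects F from subject means
        means = {g: data[g].mean(axis=1) for g in data}
        f_classic, p_classic = st_sp.f_oneway(means["c"], means["h"])
        assert res.statistic == pytest.approx(f_classic, rel=0.15)
        assert res.p_value == pytest.approx(p_classic, abs=0.02)

    def test_fewer_than_two_complete_trees_raises(self):
        panel = _panel({"c": np.random.default_rng(0).normal(size=(1, 3)),
                        "h": np.random.default_rng(1).normal(size=(4, 3))})
        with pytest.raises(ValueError, match="fewer than 2"):
            bw_trimmed_anova(panel, "m")

    def test_incomplete_subjects_dropped_with_warning(self):
        panel = _panel({"c": np.random.default_rng(0).normal(size=(5, 3)),
                        "h": np.random.default_rng(1).normal(size=(5, 3))})
        panel.loc[(panel.tree_id == "c0") & (panel.year == 2001), "m"] = np.nan
        with pytest.warns(UserWarning, match="dropped 1 subjects"):
            bw_trimmed_anova(panel, "m")

    def test_detects_strong_between_effect(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.5, (6, 5))
        b = rng.normal(3, 0.5, (6, 5))
        res = bw_trimmed_anova(_panel({"c": a, "h": b}), "m")
        assert res["treatment"].p_value < 0.001
        assert res["treatment"].stars == "***"


class TestStarsAndCorrelation:
    def test_published_star_thresholds(self):
        assert p_stars(0.0005) == "***"
        assert p_stars(0.005) == "**"
        assert p_stars(0.05) == "*"
        assert p_stars(0.2) == ""

    def test_correlation_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        panel = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        cm = correlation_table(panel, list("abc"))
        assert np.allclose(cm.rho, cm.rho.T)
        assert np.allclose(np.diag(cm.rho), 1.0)
        assert cm.n == 30
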