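"""Synthetic multi-year stem-radius and temperature series with known truth.

The generator emulates the statistical structure of high-resolution (15-min)
point-dendrometer records from slow-growing conifers in a cold climate:

* a seasonal cumulative growth curve per calendar year, Gompertz-shaped and
  reparameterized so that the day-of-year at which 5% and 95% of the annual
  increment are completed are direct inputs (the curve is normalized to start
  the year at exactly 0 and end it at exactly the configured annual growth);
* a mean-zero diurnal contraction/expansion cycle (daytime shrinkage, nightly
  recovery) with period exactly one day;
* months-long autumn–winter dehydration shrinkage that ramps in after growth
  cessation and is fully recovered during a spring rehydration window (net
  zero over a dehydration–rehydration cycle);
* Gaussian measurement noise, missing intervals (absent rows), and sensor
  readjustment jumps;
* a paired temperature series (annual sinusoid plus diurnal cycle), with the
  heated treatment offset upward during the frost-free season;
* a soil-warming treatment effect: cessation shifted earlier and growth rate
  multiplied, so that annual growth scales as rate x duration.

Every simulated tree carries a ``truth`` table with both the configured and
the *realized* per-year onset/cessation/annual-growth values, the latter
computed from the noise-free, artifact-free signal.  Realized values are the
ground truth for parameter-recovery studies: winter shrinkage hides the slow
tail of the growth curve below the running maximum, which moves the realized
threshold crossings a few days from the configured ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .series import RadiusSeries, TemperatureSeries

__all__ = [
    "HeatedEffects",
    "EffectSizes",
    "SimulationConfig",
    "SyntheticTree",
    "simulate_tree",
    "simulate_experiment",
    "simulate_metrics_panel",
    "experiment_truth_table",
]

# ln(-ln q) at the 5% / 95% completion fractions of the Gompertz CDF
_A05 = math.log(-math.log(0.05))
_A95 = math.log(-math.log(0.95))


@dataclass(frozen=True)
class HeatedEffects:
    """Treatment effect of soil warming on the growth season."""

    cessation_shift_days: float = -8.0
    rate_multiplier: float = 1.18


@dataclass(frozen=True)
class EffectSizes:
    """Random-effect standard deviations for a multi-tree experiment.

    Growth effects are on the log scale (multiplicative); onset/cessation
    effects are in days.  Year effects are shared by all trees (weather),
    tree effects are constant over years (micro-site, vigor), and residuals
    are independent per tree-year.
    """

    year_onset_sd: float = 5.0
    year_cessation_sd: float = 14.0
    year_log_growth_sd: float = 0.25
    tree_onset_sd: float = 3.0
    tree_cessation_sd: float = 6.0
    tree_log_growth_sd: float = 0.12
    resid_onset_sd: float = 3.0
    resid_cessation_sd: float = 8.0
    resid_log_growth_sd: float = 0.10


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic tree.

    ``onset_doy_true`` / ``cessation_doy_true`` are the days of year at which
    5% and 95% of the annual increment are completed (interpreted as attained
    at midday of that calendar day); scalars broadcast over years.
    ``diurnal_amplitude_um`` is peak-to-peak.  The seed fixes the output
    bit-for-bit.
    """

    seed: int = 0
    n_years: int = 3
    start_year: int = 2010
    steps_per_day: int = 96
    onset_doy_true: float | Sequence[float] = 152.0
    cessation_doy_true: float | Sequence[float] = 244.0
    annual_growth_um: float | Sequence[float] = 1160.0
    baseline_um: float = 20000.0
    diurnal_amplitude_um: float = 30.0
    winter_shrinkage_um: float = 800.0
    shrink_lag_days: float = 15.0
    shrink_ramp_days: float = 30.0
    rehydration_start_doy: float = 95.0
    rehydration_end_doy: float = 135.0
    noise_sd_um: float = 3.0
    gap_spec: tuple = ()   # (start_step, length_in_steps)
    jump_spec: tuple = ()  # (step, offset_um)
    treatment: str = "control"
    heated_effects: HeatedEffects = field(default_factory=HeatedEffects)
    dead_from_year: int | None = None  # 1-based year index; no growth after
    dead_decline_um_per_year: float = 150.0
    min_annual_growth_um: float = 30.0
    # temperature model
    temp_mean_c: float = 2.0
    temp_annual_amplitude_c: float = 16.0
    temp_diurnal_amplitude_c: float = 3.0
    temp_noise_sd_c: float = 1.0
    heated_temp_offset_c: float = 4.0

    def per_year(self, name: str) -> np.ndarray:
        val = getattr(self, name)
        arr = np.broadcast_to(np.asarray(val, dtype=float), (self.n_years,))
        return np.array(arr, dtype=float)

    def validate(self) -> None:
        onset = self.per_year("onset_doy_true")
        cess = self.per_year("cessation_doy_true")
        growth = self.per_year("annual_growth_um")
        scalars = [
            self.diurnal_amplitude_um,
            self.winter_shrinkage_um,
            self.noise_sd_um,
            self.shrink_lag_days,
            self.shrink_ramp_days,
            self.rehydration_start_doy,
            self.rehydration_end_doy,
        ]
        for arr in (onset, cess, growth, np.asarray(scalars, dtype=float)):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite simulation parameter")
        if np.any(onset >= cess):
            raise ValueError("onset_doy_true must be < cessation_doy_true in every year")
        if np.any(growth < 0):
            raise ValueError("annual_growth_um must be >= 0")
        if self.diurnal_amplitude_um < 0 or self.winter_shrinkage_um < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd_um < 0:
            raise ValueError("noise_sd_um must be >= 0")
        if not self.rehydration_start_doy < self.rehydration_end_doy:
            raise ValueError("rehydration window must have positive length")
        if self.winter_shrinkage_um > 0 and self.rehydration_end_doy > onset.min() - 5:
            raise ValueError(
                "rehydration window overlaps the growth onset window; "
                "ground truth would be ambiguous"
            )
        if 1440 % self.steps_per_day != 0:
            raise ValueError("steps_per_day must divide 1440")
        if self.treatment not in ("control", "heated"):
            raise ValueError("treatment must be 'control' or 'heated'")


@dataclass
class SyntheticTree:
    """A simulated tree: signal, paired temperature, and its ground truth."""

    radius_series: RadiusSeries
    temperature_series: TemperatureSeries
    config: SimulationConfig
    truth: pd.DataFrame  # one row per measurable season (years 2..n)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _solve_gompertz(t1: float, t2: float, ndays: int) -> tuple[float, float, float, float]:
    """Gompertz parameters such that the curve, normalized to rise from 0 at
    the start of the year to 1 at its end, passes through (t1, 0.05) and
    (t2, 0.95).  Returns (k, tm, g0, gspan) for normalized evaluation."""

    def raw(t, k, tm):
        return np.exp(-np.exp(-k * (t - tm)))

    # closed form ignoring the (tiny) normalization
    k0 = (_A05 - _A95) / (t2 - t1)
    tm0 = t1 + _A05 / k0

    def resid(p):
        k, tm = p
        g0 = raw(0.0, k, tm)
        span = raw(float(ndays), k, tm) - g0
        return [
            (raw(t1, k, tm) - g0) / span - 0.05,
            (raw(t2, k, tm) - g0) / span - 0.95,
        ]

    sol, info, ok, _ = optimize.fsolve(resid, [k0, tm0], full_output=True)
    if ok != 1 or not np.all(np.isfinite(sol)):
        sol = (k0, tm0)
    k, tm = float(sol[0]), float(sol[1])
    g0 = raw(0.0, k, tm)
    gspan = raw(float(ndays), k, tm) - g0
    return k, tm, g0, gspan


def _days_in_year(year: int) -> int:
    return 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365


def _growth_signal(cfg: SimulationConfig, years: np.ndarray, tau: np.ndarray,
                   year_list: list[int]) -> np.ndarray:
    """Cumulative growth (µm above baseline) on the full time grid."""
    onset = cfg.per_year("onset_doy_true")
    cess = cfg.per_year("cessation_doy_true")
    growth = cfg.per_year("annual_growth_um")
    out = np.zeros_like(tau)
    base = 0.0
    for i, yr in enumerate(year_list):
        mask = years == yr
        ndays = _days_in_year(yr)
        t = tau[mask]
        dead = cfg.dead_from_year is not None and (i + 1) >= cfg.dead_from_year
        if dead or growth[i] == 0:
            decline = cfg.dead_decline_um_per_year if dead else 0.0
            out[mask] = base - decline * t / ndays
            base -= decline
            continue
        # configured DOY d means the fraction is attained at midday of day d
        k, tm, g0, gspan = _solve_gompertz(onset[i] - 0.5, cess[i] - 0.5, ndays)
        frac = (np.exp(-np.exp(-k * (t - tm))) - g0) / gspan
        out[mask] = base + growth[i] * frac
        base += growth[i]
    return out


def _winter_deficit(cfg: SimulationConfig, years: np.ndarray, tau: np.ndarray,
                    year_list: list[int]) -> np.ndarray:
    """Reversible dehydration deficit (µm, >= 0) subtracted from the signal."""
    w = cfg.winter_shrinkage_um
    if w == 0:
        return np.zeros_like(tau)
    cess = cfg.per_year("cessation_doy_true")
    rs, re = cfg.rehydration_start_doy - 1.0, cfg.rehydration_end_doy - 1.0
    out = np.zeros_like(tau)
    for i, yr in enumerate(year_list):
        mask = years == yr
        t = tau[mask]
        ndays = _days_in_year(yr)
        deh_start = cess[i] - 1.0 + cfg.shrink_lag_days
        deh_end = min(deh_start + cfg.shrink_ramp_days, ndays - 1.0)
        d = np.where(t < re, w * (1.0 - _smoothstep((t - rs) / (re - rs))), 0.0)
        d = d + w * _smoothstep((t - deh_start) / (deh_end - deh_start))
        out[mask] = d
    return out


def _realized_truth(cfg: SimulationConfig, index: pd.DatetimeIndex,
                    clean: np.ndarray, series_id: str) -> pd.DataFrame:
    """Per-year realized onset/cessation/growth from the noise-free signal.

    Uses the zero-growth definitions directly (previous calendar-year maximum
    as reference, 5%/95% completion thresholds) with plain numpy, keeping the
    truth independent of the phenology extraction code it will be compared to.
    """
    years = index.year.to_numpy()
    doys = index.dayofyear.to_numpy()
    onset_cfg = cfg.per_year("onset_doy_true")
    cess_cfg = cfg.per_year("cessation_doy_true")
    growth_cfg = cfg.per_year("annual_growth_um")
    year_list = [cfg.start_year + i for i in range(cfg.n_years)]
    rows = []
    for i in range(1, cfg.n_years):
        yr = year_list[i]
        prev = clean[years == yr - 1]
        cur_mask = years == yr
        cur = clean[cur_mask]
        cur_doys = doys[cur_mask]
        pm, cm = prev.max(), cur.max()
        g = cm - pm
        row = {
            "series_id": series_id, "year": yr, "treatment": cfg.treatment,
            "onset_cfg": onset_cfg[i], "cessation_cfg": cess_cfg[i],
            "growth_cfg_um": growth_cfg[i],
            "onset_true": np.nan, "cessation_true": np.nan,
            "growth_true_um": g, "max_doy_true": np.nan,
            "valid_true": False,
        }
        if g > cfg.min_annual_growth_um:
            onset_idx = int(np.argmax(cur >= pm + 0.05 * g))
            cess_idx = int(np.argmax(cur >= pm + 0.95 * g))
            row.update(
                onset_true=int(cur_doys[onset_idx]),
                cessation_true=int(cur_doys[cess_idx]),
                max_doy_true=int(cur_doys[int(np.argmax(cur))]),
                valid_true=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_tree(config: SimulationConfig, series_id: str | None = None) -> SyntheticTree:
    """Simulate one tree's radius and temperature series with ground truth."""
    config.validate()
    cfg = config
    sid = series_id or f"sim{cfg.seed:04d}"
    year_list = [cfg.start_year + i for i in range(cfg.n_years)]
    step_min = 1440 // cfg.steps_per_day
    index = pd.date_range(
        pd.Timestamp(year=year_list[0], month=1, day=1),
        pd.Timestamp(year=year_list[-1], month=12, day=31, hour=23, minute=60 - step_min),
        freq=f"{step_min}min",
    )
    years = index.year.to_numpy()
    frac = (index.hour.to_numpy() * 60 + index.minute.to_numpy()) / 1440.0
    tau = (index.dayofyear.to_numpy() - 1) + frac

    growth = _growth_signal(cfg, years, tau, year_list)
    # daytime contraction / nightly recovery, mean-zero over any whole day
    diurnal = 0.5 * cfg.diurnal_amplitude_um * np.cos(2 * np.pi * (frac - 14.0 / 24.0))
    deficit = _winter_deficit(cfg, years, tau, year_list)
    clean = cfg.baseline_um + growth - diurnal - deficit

    truth = _realized_truth(cfg, index, clean, sid)

    rng = np.random.default_rng(cfg.seed)
    radius = clean.copy()
    if cfg.noise_sd_um > 0:
        radius = radius + rng.normal(0.0, cfg.noise_sd_um, radius.size)
    for step, offset in cfg.jump_spec:
        radius[int(step):] += float(offset)
    keep = np.ones(radius.size, dtype=bool)
    for start, length in cfg.gap_spec:
        keep[int(start):int(start) + int(length)] = False

    rframe = pd.DataFrame({"value": radius}, index=index)[keep]
    rseries = RadiusSeries(sid, rframe)

    seas = cfg.temp_mean_c + cfg.temp_annual_amplitude_c * np.sin(
        2 * np.pi * (tau - 105.0) / 365.25)
    tdiurnal = cfg.temp_diurnal_amplitude_c * np.cos(2 * np.pi * (frac - 15.0 / 24.0))
    temp = seas + tdiurnal
    if cfg.treatment == "heated":
        # warming cables run from snowmelt to the first autumn frosts
        temp = temp + cfg.heated_temp_offset_c * (seas > 0.0)
    if cfg.temp_noise_sd_c > 0:
        temp = temp + rng.normal(0.0, cfg.temp_noise_sd_c, temp.size)
    tseries = TemperatureSeries(sid, pd.DataFrame({"temp_c": temp}, index=index)[keep])

    return SyntheticTree(rseries, tseries, cfg, truth)


# ---------------------------------------------------------------------------
# Multi-tree experiment


def _draw_season_params(rng: np.random.Generator, n_control: int, n_heated: int,
                        n_seasons: int, base: SimulationConfig,
                        heated_effects: HeatedEffects,
                        effects: EffectSizes) -> list[dict]:
    """Per-tree dicts of per-year onset/cessation/growth with shared year
    effects, tree effects, residuals, and the heated-treatment contrast."""
    e = effects
    base_onset = float(np.mean(base.per_year("onset_doy_true")))
    base_cess = float(np.mean(base.per_year("cessation_doy_true")))
    base_growth = float(np.mean(base.per_year("annual_growth_um")))
    yo = rng.normal(0, e.year_onset_sd, n_seasons)
    yc = rng.normal(0, e.year_cessation_sd, n_seasons)
    yg = rng.normal(0, e.year_log_growth_sd, n_seasons)
    out = []
    labels = ["control"] * n_control + ["heated"] * n_heated
    for t, treatment in enumerate(labels):
        to = rng.normal(0, e.tree_onset_sd)
        tc = rng.normal(0, e.tree_cessation_sd)
        tg = rng.normal(0, e.tree_log_growth_sd)
        onset = base_onset + yo + to + rng.normal(0, e.resid_onset_sd, n_seasons)
        cess = base_cess + yc + tc + rng.normal(0, e.resid_cessation_sd, n_seasons)
        # onset cannot precede the end of spring rehydration (plus margin)
        onset_floor = base.rehydration_end_doy + 6.0 if base.winter_shrinkage_um > 0 else 115.0
        onset = np.clip(onset, onset_floor, None)
        cess_c = np.clip(cess, onset + 40.0, 300.0)
        growth = base_growth * np.exp(yg + tg + rng.normal(0, e.resid_log_growth_sd, n_seasons))
        if treatment == "heated":
            cess_h = np.clip(cess_c + heated_effects.cessation_shift_days,
                             onset + 40.0, 300.0)
            # growth = rate x duration: rate multiplied, duration shifted
            growth = growth * heated_effects.rate_multiplier * (cess_h - onset) / (cess_c - onset)
            cess = cess_h
        else:
            cess = cess_c
        out.append({
            "treatment": treatment,
            "onset": onset, "cessation": cess, "growth": growth,
            "tree_id": f"{'C' if treatment == 'control' else 'H'}{t + 1:02d}",
        })
    return out


def simulate_experiment(n_control: int = 6, n_heated: int = 6, years: int = 12,
                        base: SimulationConfig | None = None,
                        heated_effects: HeatedEffects | None = None,
                        seed: int = 0,
                        effects: EffectSizes | None = None,
                        burn_in_years: int = 1,
                        dead: dict[int, int] | None = None) -> list[SyntheticTree]:
    """Simulate a soil-warming experiment.

    ``years`` counts measurable seasons; one extra burn-in calendar year is
    prepended by default so the first measurable season has a previous-year
    maximum to reference.  ``dead`` optionally maps a tree position (0-based,
    controls first) to the 1-based measurable season from which that tree is
    dead (no growth, slow radial decline) — for exercising the
    "no valid season" path.
    """
    if n_control < 1 or n_heated < 1 or years < 1:
        raise ValueError("counts must be >= 1")
    base = base or SimulationConfig()
    heated_effects = heated_effects or base.heated_effects
    effects = effects or EffectSizes()
    n_cal = years + burn_in_years
    rng = np.random.default_rng(seed)
    params = _draw_season_params(rng, n_control, n_heated, n_cal, base,
                                 heated_effects, effects)
    trees = []
    for i, p in enumerate(params):
        cfg = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_years=n_cal,
            onset_doy_true=tuple(p["onset"]),
            cessation_doy_true=tuple(p["cessation"]),
            annual_growth_um=tuple(p["growth"]),
            treatment=p["treatment"],
            heated_effects=heated_effects,
            dead_from_year=(dead[i] + burn_in_years) if dead and i in dead else None,
        )
        trees.append(simulate_tree(cfg, series_id=p["tree_id"]))
    return trees


def experiment_truth_table(trees: list[SyntheticTree]) -> pd.DataFrame:
    """Stack the per-tree ground-truth tables into one tidy table."""
    return pd.concat([t.truth for t in trees], ignore_index=True)


def simulate_metrics_panel(n_control: int = 6, n_heated: int = 6, years: int = 12,
                           base: SimulationConfig | None = None,
                           heated_effects: HeatedEffects | None = None,
                           seed: int = 0,
                           effects: EffectSizes | None = None,
                           tol_seas: float = 0.05) -> pd.DataFrame:
    """Draw a season-metrics panel directly from the random-effects model.

    Produces the same per-tree-year stochastic structure the full simulator
    feeds into its signals, without synthesizing 15-min series — suitable for
    large Monte Carlo studies of the statistical layer (type-I error, power).
    Total growth is the threshold-to-threshold span, (1 - 2q) of the annual
    increment.
    """
    base = base or SimulationConfig()
    heated_effects = heated_effects or base.heated_effects
    effects = effects or EffectSizes()
    rng = np.random.default_rng(seed)
    params = _draw_season_params(rng, n_control, n_heated, years, base,
                                 heated_effects, effects)
    rows = []
    for p in params:
        duration = p["cessation"] - p["onset"]
        total = (1.0 - 2.0 * tol_seas) * p["growth"]
        for y in range(years):
            rows.append({
                "tree_id": p["tree_id"], "treatment": p["treatment"],
                "year": base.start_year + y,
                "onset": p["onset"][y], "cessation": p["cessation"][y],
                "duration": duration[y], "total": total[y],
                "rate": total[y] / duration[y],
            })
    return pd.DataFrame(rows)
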