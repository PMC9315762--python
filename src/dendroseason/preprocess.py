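"""Cleaning of raw dendrometer series before ZG decomposition.

The stages mirror standard dendrometer processing practice: temporal
alignment onto an exact grid, linear interpolation of short gaps (runs of
fewer than three missing steps by default), frost-period flagging from a
paired temperature record (points in frost are exempt from outlier removal,
since frost shrinkage is real signal, not error), and correction of sensor
artifacts — single-point spikes are removed and re-interpolated, and step
changes from dendrometer readjustment or replacement are subtracted from all
subsequent values so that cumulative growth is preserved.

Artifact detection is based on first differences compared against a robust
(median-absolute-deviation) scale estimated per calendar day, which makes it
insensitive to the diurnal cycle.  The rigidity of the spike and jump tests
is controlled by the ``tol_out`` and ``tol_jump`` multipliers.  In place of
a manual visual-validation pass, an error is raised when more than a small
fraction of points would be altered, as a guardrail for pathological input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import (
    FLAG_FROST,
    FLAG_INTERPOLATED,
    FLAG_JUMP_CORRECTED,
    FLAG_OUTLIER_REMOVED,
    RadiusSeries,
    TemperatureSeries,
    add_flag,
)

__all__ = [
    "CleaningParams",
    "CleaningError",
    "regularize",
    "fill_gaps",
    "flag_frost",
    "correct_jumps_and_outliers",
    "clean",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleaningParams:
    interval_minutes: int = 15
    max_gap_steps: int = 2          # gaps of fewer than 3 steps are filled
    tol_jump: float = 50.0
    tol_out: float = 10.0
    frost_temp_c: float = 5.0
    frost_pad_steps: int = 2
    max_flagged_fraction: float = 0.05
    min_scale_um: float = 0.1       # floor for the robust difference scale

    def __post_init__(self) -> None:
        if min(self.interval_minutes, self.tol_jump, self.tol_out) <= 0:
            raise ValueError("cleaning parameters must be positive")
        if self.max_gap_steps < 0 or self.frost_pad_steps < 0:
            raise ValueError("step counts must be >= 0")


class CleaningError(ValueError):
    pass


def regularize(raw: RadiusSeries, params: CleaningParams = CleaningParams()) -> RadiusSeries:
    """Snap observations onto an exact grid spanning first to last timestamp.

    Each grid point takes the raw observation within half an interval of it;
    grid points with no observation are missing.  Two observations snapping
    to the same grid cell are an error (the input is ambiguous).
    """
    if len(raw) == 0:
        raise CleaningError("empty input series")
    freq = f"{params.interval_minutes}min"
    snapped = raw.frame.index.round(freq)
    if snapped.has_duplicates:
        dups = snapped[snapped.duplicated()].unique()
        raise CleaningError(
            f"{raw.series_id}: multiple observations snap to grid cell(s) "
            f"{[str(t) for t in dups[:5]]}")
    frame = raw.frame.copy()
    frame.index = snapped
    grid = pd.date_range(snapped[0], snapped[-1], freq=freq)
    frame = frame.reindex(grid)
    frame["flag"] = frame["flag"].fillna("")
    frame.loc[frame["value"].isna(), "flag"] = ""
    return RadiusSeries(raw.series_id, frame)


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each run of True in a boolean mask."""
    changes = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(changes == 1) + 1)
    ends = list(np.flatnonzero(changes == -1) + 1)
    if mask.size and mask[0]:
        starts = [0] + starts
    if mask.size and mask[-1]:
        ends = ends + [mask.size]
    return [(s, e - s) for s, e in zip(starts, ends)]


def fill_gaps(s: RadiusSeries, params: CleaningParams = CleaningParams()) -> RadiusSeries:
    """Linearly interpolate missing runs of at most ``max_gap_steps``.

    Longer runs, and leading/trailing missing values, are left missing.
    """
    frame = s.frame.copy()
    v = frame["value"].to_numpy(dtype=float)
    missing = np.isnan(v)
    if not missing.any():
        return RadiusSeries(s.series_id, frame)
    interp = frame["value"].interpolate(method="time", limit_area="inside")
    filled = np.zeros(v.size, dtype=bool)
    for start, length in _missing_runs(missing):
        if length <= params.max_gap_steps and start > 0 and start + length < v.size:
            filled[start:start + length] = True
    v[filled] = interp.to_numpy()[filled]
    frame["value"] = v
    add_flag(frame, filled, FLAG_INTERPOLATED)
    n = int(filled.sum())
    if n:
        log.info("%s: interpolated %d points in short gaps", s.series_id, n)
    return RadiusSeries(s.series_id, frame)


def flag_frost(s: RadiusSeries, t: TemperatureSeries | None,
               params: CleaningParams = CleaningParams()) -> RadiusSeries:
    """Flag points whose (nearest-neighbour regridded) temperature is below
    the frost threshold, padded symmetrically; strict inequality at the
    threshold.  Without a temperature record no flags are set (warning)."""
    frame = s.frame.copy()
    if t is None or len(t) == 0:
        log.warning("%s: no temperature record; frost periods not flagged",
                    s.series_id)
        return RadiusSeries(s.series_id, frame)
    tol = pd.Timedelta(minutes=params.interval_minutes)
    temp = t.temps.reindex(frame.index, method="nearest", tolerance=tol)
    cold = (temp < params.frost_temp_c).to_numpy()
    if params.frost_pad_steps > 0:
        w = 2 * params.frost_pad_steps + 1
        cold = (pd.Series(cold.astype(int)).rolling(w, center=True, min_periods=1)
                .max().to_numpy() > 0)
    add_flag(frame, cold, FLAG_FROST)
    return RadiusSeries(s.series_id, frame)


def _daily_robust_scale(index: pd.DatetimeIndex, d: np.ndarray,
                        params: CleaningParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (median, MAD-scale) of first differences, by calendar day.

    Robust to the diurnal cycle at 15-min resolution: within a day the
    diurnal contribution to each difference is nearly constant in magnitude
    compared to a sensor artifact.  Falls back to the global statistics on
    days with too few finite differences.
    """
    days = index[1:].normalize()
    df = pd.DataFrame({"d": d}, index=days)
    grouped = df.groupby(level=0)["d"]
    med = grouped.transform("median").to_numpy()

    def _mad(x: np.ndarray) -> float:
        x = x[np.isfinite(x)]
        if x.size == 0:
            return np.nan
        m = np.median(x)
        return float(np.median(np.abs(x - m)))

    mad = grouped.transform(lambda x: _mad(x.to_numpy()))
    scale = 1.4826 * mad.to_numpy()
    finite = np.isfinite(d)
    gmed = np.nanmedian(d[finite]) if finite.any() else 0.0
    gmad = (1.4826 * np.nanmedian(np.abs(d[finite] - gmed))) if finite.any() else 0.0
    med = np.where(np.isfinite(med), med, gmed)
    scale = np.where(np.isfinite(scale) & (scale > 0), scale, gmad)
    scale = np.maximum(scale, params.min_scale_um)
    return med, scale


def correct_jumps_and_outliers(s: RadiusSeries,
                               params: CleaningParams = CleaningParams()
                               ) -> RadiusSeries:
    """Remove single-point spikes and subtract sensor-shift offsets.

    A first difference whose deviation from the local median exceeds
    ``tol_out`` x robust scale and is immediately reversed is a spike: the
    point is removed and re-interpolated.  A deviation exceeding ``tol_jump``
    x robust scale without reversal is a sensor shift: the offset (in excess
    of the locally expected difference) is subtracted from all subsequent
    values, so non-artifact differences are preserved exactly.  Frost-flagged
    points are exempt from spike removal.  An error is raised if more than
    ``max_flagged_fraction`` of the points would be altered.
    """
    frame = s.frame.copy()
    v = frame["value"].to_numpy(dtype=float)
    if v.size < 3:
        return RadiusSeries(s.series_id, frame)
    d = np.diff(v)
    med, scale = _daily_robust_scale(frame.index, d, params)
    dev = d - med
    frost = s.has_flag(FLAG_FROST).to_numpy() if "flag" in frame else np.zeros(v.size, bool)
    low_tol = min(params.tol_out, params.tol_jump)
    candidates = np.flatnonzero(np.abs(dev) > low_tol * scale)
    spike_idx: list[int] = []
    jump_idx: list[int] = []
    handled: set[int] = set()
    for i in candidates:
        if i in handled or not np.isfinite(dev[i]):
            continue
        is_spike = (
            np.abs(dev[i]) > params.tol_out * scale[i]
            and i + 1 < d.size
            and np.isfinite(dev[i + 1])
            and np.abs(dev[i] + dev[i + 1]) < 0.5 * np.abs(dev[i])
            and not frost[i + 1]
        )
        if is_spike:
            spike_idx.append(i + 1)
            handled.update({i, i + 1})
        elif np.abs(dev[i]) > params.tol_jump * scale[i]:
            jump_idx.append(i + 1)
            handled.add(i)
    n_flagged = len(spike_idx) + len(jump_idx)
    if n_flagged > params.max_flagged_fraction * v.size:
        raise CleaningError(
            f"{s.series_id}: {n_flagged} of {v.size} points flagged as "
            "artifacts; inspect the series manually")
    for p in jump_idx:
        v[p:] -= dev[p - 1]
    spikes = np.zeros(v.size, dtype=bool)
    spikes[spike_idx] = True
    v[spikes] = np.nan
    frame["value"] = v
    if spikes.any():
        interp = frame["value"].interpolate(method="time", limit_area="inside")
        frame.loc[spikes, "value"] = interp[spikes]
        add_flag(frame, spikes, FLAG_OUTLIER_REMOVED)
    jumps = np.zeros(v.size, dtype=bool)
    jumps[jump_idx] = True
    add_flag(frame, jumps, FLAG_JUMP_CORRECTED)
    if n_flagged:
        log.info("%s: removed %d spikes, corrected %d jumps",
                 s.series_id, len(spike_idx), len(jump_idx))
    return RadiusSeries(s.series_id, frame)


def clean(raw: RadiusSeries, temperature: TemperatureSeries | None = None,
          params: CleaningParams = CleaningParams()) -> RadiusSeries:
    """Full cleaning pipeline: regularize, frost-flag, correct, fill gaps."""
    s = regularize(raw, params)
    s = flag_frost(s, temperature, params)
    s = correct_jumps_and_outliers(s, params)
    s = fill_gaps(s, params)
    return s
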