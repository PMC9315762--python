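"""Growth-phenology metrics per tree-year from a ZG decomposition.

For a calendar year with previous-year maximum ``prev_max`` and current-year
maximum ``curr_max``, the annual growth is G = curr_max - prev_max.  At a
tolerance fraction q (``tol_seas``):

* growth onset   = first DOY with radius >= prev_max + q * G,
* growth cessation = first DOY with radius >= prev_max + (1 - q) * G,
* duration = cessation - onset (days, same q),
* total growth = radius at the cessation crossing minus radius at the onset
  crossing (the default "threshold_span" mode; "max_to_max" reports G),
* rate = total growth / duration (µm/day).

The tolerance absorbs the asymptotic shape of the seasonal curve and erratic
late-season fluctuations: raising q mainly stabilizes the dating of growth
cessation, which otherwise hinges on a single high-resolution observation.

Seasons are invalid (with a reason code, no numeric metrics) when the
previous reference year is missing, when net annual growth is not positive,
or when the year contains a sensor break — a missing run longer than the
season-breaking length — that makes the record unjoinable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .zero_growth import ZGDecomposition

__all__ = [
    "SeasonParams",
    "SeasonError",
    "annual_maximum",
    "growth_onset",
    "growth_cessation",
    "season_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class SeasonParams:
    """Tolerances and validity rules for season extraction."""

    tol_seas: tuple[float, ...] = (0.05, 0.10, 0.20)
    min_annual_growth_um: float = 30.0
    season_break_days: float = 30.0
    min_coverage: float = 0.5  # fraction of the year that must be observed
    total_growth_mode: str = "threshold_span"  # or "max_to_max"

    def __post_init__(self) -> None:
        for q in self.tol_seas:
            if not 0.0 <= q < 0.5:
                raise ValueError("tol_seas fractions must be in [0, 0.5)")
        if self.total_growth_mode not in ("threshold_span", "max_to_max"):
            raise ValueError("unknown total_growth_mode")


class SeasonError(ValueError):
    """A season that cannot be characterized; carries a reason code."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


def _year_slice(z: ZGDecomposition, year: int) -> pd.DataFrame:
    sub = z.frame[z.frame.index.year == year]
    if len(sub) == 0 or sub["value"].notna().sum() == 0:
        raise SeasonError("year_missing", f"year {year} has no observations")
    return sub


def annual_maximum(z: ZGDecomposition, year: int) -> tuple[int, float]:
    """(DOY, value) of the year's maximum radius; first occurrence wins."""
    sub = _year_slice(z, year)
    v = sub["value"]
    value = float(v.max())
    ts = v.idxmax()  # first occurrence of the maximum
    return int(ts.dayofyear), value


def _longest_missing_run_days(sub: pd.DataFrame) -> float:
    ok = sub["value"].notna().to_numpy()
    if ok.all():
        return 0.0
    idx = sub.index
    step = (idx[1] - idx[0]) if len(idx) > 1 else pd.Timedelta(minutes=15)
    # run lengths of consecutive missing points
    missing = ~ok
    changes = np.diff(missing.astype(int))
    starts = np.flatnonzero(changes == 1) + 1
    ends = np.flatnonzero(changes == -1) + 1
    if missing[0]:
        starts = np.r_[0, starts]
    if missing[-1]:
        ends = np.r_[ends, missing.size]
    longest = int((ends - starts).max())
    return longest * step / pd.Timedelta(days=1)


def _season_reference(z: ZGDecomposition, year: int,
                      params: SeasonParams) -> tuple[float, float, float]:
    """(prev_max, curr_max, G) with the validity gates applied."""
    try:
        _, prev_max = annual_maximum(z, year - 1)
    except SeasonError:
        raise SeasonError("no_reference_year",
                          f"no previous-year maximum for {year}") from None
    sub = _year_slice(z, year)
    if _longest_missing_run_days(sub) > params.season_break_days:
        raise SeasonError("sensor_break",
                          f"missing run exceeds {params.season_break_days} days in {year}")
    if sub["value"].notna().mean() < params.min_coverage:
        raise SeasonError("insufficient_coverage", f"sparse record in {year}")
    curr_max = float(sub["value"].max())
    g = curr_max - prev_max
    if g <= params.min_annual_growth_um:
        raise SeasonError("no_net_growth",
                          f"annual growth {g:.1f} µm not above threshold in {year}")
    return prev_max, curr_max, g


def _first_crossing(sub: pd.DataFrame, threshold: float) -> tuple[int, float]:
    v = sub["value"]
    hit = v[v >= threshold]
    if len(hit) == 0:
        raise SeasonError("season_incomplete",
                          "threshold not attained within the calendar year")
    ts = hit.index[0]
    return int(ts.dayofyear), float(hit.iloc[0])


def growth_onset(z: ZGDecomposition, year: int, q: float,
                 params: SeasonParams = SeasonParams()) -> int:
    """DOY at which q of the annual growth above the previous-year maximum
    is first completed (q -> 0: first exceedance of the previous maximum)."""
    prev_max, _, g = _season_reference(z, year, params)
    doy, _ = _first_crossing(_year_slice(z, year), prev_max + q * g)
    return doy


def growth_cessation(z: ZGDecomposition, year: int, q: float,
                     params: SeasonParams = SeasonParams()) -> int:
    """DOY at which (1 - q) of the annual growth is first completed."""
    prev_max, _, g = _season_reference(z, year, params)
    doy, _ = _first_crossing(_year_slice(z, year), prev_max + (1.0 - q) * g)
    return doy


def season_metrics(z: ZGDecomposition, year: int,
                   params: SeasonParams = SeasonParams()) -> pd.DataFrame:
    """Season metrics for one tree-year, one row per tolerance q.

    Invalid seasons yield rows (one per q) with ``valid=False``, a reason
    code, and NaN metrics, so downstream accounting sees every tree-year.
    """
    base = {"series_id": z.series_id, "year": year}
    try:
        prev_max, curr_max, g = _season_reference(z, year, params)
    except SeasonError as err:
        rows = [dict(base, q=q, valid=False, reason=err.reason,
                     prev_max_um=np.nan, curr_max_um=np.nan, curr_max_doy=np.nan,
                     annual_growth_um=np.nan, onset_doy=np.nan, cessation_doy=np.nan,
                     duration_days=np.nan, total_growth_um=np.nan,
                     rate_um_per_day=np.nan)
                for q in params.tol_seas]
        return pd.DataFrame(rows)
    sub = _year_slice(z, year)
    max_doy, _ = annual_maximum(z, year)
    rows = []
    for q in params.tol_seas:
        onset_doy, onset_val = _first_crossing(sub, prev_max + q * g)
        cess_doy, cess_val = _first_crossing(sub, prev_max + (1.0 - q) * g)
        duration = cess_doy - onset_doy
        if params.total_growth_mode == "threshold_span":
            total = cess_val - onset_val
        else:
            total = g
        rate = total / duration if duration > 0 else np.nan
        rows.append(dict(base, q=q, valid=True, reason="",
                         prev_max_um=prev_max, curr_max_um=curr_max,
                         curr_max_doy=max_doy, annual_growth_um=g,
                         onset_doy=onset_doy, cessation_doy=cess_doy,
                         duration_days=duration, total_growth_um=total,
                         rate_um_per_day=rate))
    return pd.DataFrame(rows)


def metrics_table(decompositions: Iterable[ZGDecomposition],
                  params: SeasonParams = SeasonParams(),
                  treatments: dict[str, str] | None = None) -> pd.DataFrame:
    """Season metrics for every series and every measurable calendar year.

    Metrics start in each series' second calendar year (the first year only
    provides the reference maximum).  ``treatments`` optionally maps
    series_id to a treatment label added as a column.
    """
    frames = []
    for z in decompositions:
        yrs = sorted(set(z.frame.index.year))
        for year in yrs[1:]:
            frames.append(season_metrics(z, year, params))
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    if treatments is not None:
        out.insert(1, "treatment", out["series_id"].map(treatments))
    return out
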