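"""Time-series containers for dendrometer records.

A stem-radius record is a regularly (or nearly regularly) sampled series of
radius values in micrometres, together with per-point quality flags.  A
temperature record carries degrees Celsius on the same kind of grid.  Both
are thin dataclass wrappers around a :class:`pandas.DataFrame` indexed by
timestamp, which keeps the whole toolchain in ordinary pandas idiom.

Flags are comma-free tokens stored in a single string column, ``|``-joined
when a point carries more than one (e.g. ``"observed|frost"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FLAG_OBSERVED = "observed"
FLAG_INTERPOLATED = "interpolated"
FLAG_OUTLIER_REMOVED = "outlier_removed"
FLAG_JUMP_CORRECTED = "jump_corrected"
FLAG_FROST = "frost"

_KNOWN_FLAGS = {
    FLAG_OBSERVED,
    FLAG_INTERPOLATED,
    FLAG_OUTLIER_REMOVED,
    FLAG_JUMP_CORRECTED,
    FLAG_FROST,
}


def _check_index(index: pd.Index) -> None:
    if not isinstance(index, pd.DatetimeIndex):
        raise TypeError("series frame must be indexed by a DatetimeIndex")
    if len(index) > 1 and not index.is_monotonic_increasing:
        raise ValueError("timestamps must be increasing")
    if index.has_duplicates:
        dups = index[index.duplicated()].unique()
        raise ValueError(f"duplicate timestamps: {list(dups[:5])}")


@dataclass
class RadiusSeries:
    """Stem-radius series (µm) for one tree, with per-point quality flags."""

    series_id: str
    frame: pd.DataFrame  # index: timestamp; columns: value (µm), flag (str)

    def __post_init__(self) -> None:
        if "value" not in self.frame.columns:
            raise ValueError("frame must have a 'value' column")
        _check_index(self.frame.index)
        if "flag" not in self.frame.columns:
            flags = np.where(self.frame["value"].notna(), FLAG_OBSERVED, "")
            self.frame = self.frame.assign(flag=flags)
        self.frame.index.name = "timestamp"

    @property
    def values(self) -> pd.Series:
        return self.frame["value"]

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    def has_flag(self, token: str) -> pd.Series:
        """Boolean mask of the points carrying ``token``."""
        if token not in _KNOWN_FLAGS:
            raise ValueError(f"unknown flag {token!r}")
        return self.frame["flag"].str.contains(token, regex=False)

    def copy(self) -> "RadiusSeries":
        return RadiusSeries(self.series_id, self.frame.copy())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TemperatureSeries:
    """Air (or data-logger) temperature series in °C."""

    series_id: str
    frame: pd.DataFrame  # index: timestamp; column: temp_c

    def __post_init__(self) -> None:
        if "temp_c" not in self.frame.columns:
            raise ValueError("frame must have a 'temp_c' column")
        _check_index(self.frame.index)
        self.frame.index.name = "timestamp"

    @property
    def temps(self) -> pd.Series:
        return self.frame["temp_c"]

    def __len__(self) -> int:
        return len(self.frame)


def add_flag(frame: pd.DataFrame, mask, token: str) -> None:
    """Append ``token`` (in place) to the flag string of masked rows."""
    if token not in _KNOWN_FLAGS:
        raise ValueError(f"unknown flag {token!r}")
    mask = np.asarray(mask, dtype=bool)
    cur = frame["flag"].to_numpy(dtype=object)
    has = frame["flag"].str.contains(token, regex=False).to_numpy()
    sel = mask & ~has
    cur[sel] = np.where(cur[sel] == "", token, cur[sel] + "|" + token)
    frame["flag"] = cur.astype(str)


# ---------------------------------------------------------------------------
# CSV I/O — columns `series_id,timestamp,value[,flag]` / `series_id,timestamp,temp_c`


def write_radius_csv(series: RadiusSeries, path: str | Path) -> None:
    out = series.frame.reset_index()
    out.insert(0, "series_id", series.series_id)
    out["value"] = out["value"].round(1)  # sensors resolve ~0.1 µm
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_radius_csv(path: str | Path) -> RadiusSeries:
    raw = pd.read_csv(path, parse_dates=["timestamp"])
    ids = raw["series_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected one series per file, found {list(ids)}")
    frame = raw.set_index("timestamp")[["value"] + (["flag"] if "flag" in raw else [])]
    if "flag" in frame:
        frame["flag"] = frame["flag"].fillna("")
    return RadiusSeries(str(ids[0]), frame)


def write_temperature_csv(series: TemperatureSeries, path: str | Path) -> None:
    out = series.frame.reset_index()
    out.insert(0, "series_id", series.series_id)
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_temperature_csv(path: str | Path) -> TemperatureSeries:
    raw = pd.read_csv(path, parse_dates=["timestamp"])
    ids = raw["series_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected one series per file, found {list(ids)}")
    return TemperatureSeries(str(ids[0]), raw.set_index("timestamp")[["temp_c"]])
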