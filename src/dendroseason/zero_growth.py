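"""Zero-growth (ZG) decomposition of a stem-radius series.

Under the ZG concept, no irreversible growth occurs while the stem is below
its precedent maximum radius.  The signal r_t is therefore split into

* the running maximum M_t = max(M_{t-1}, r_t),
* growth increments g_t = M_t - M_{t-1} >= 0 (the GRO signal, cumulable
  to annual growth), and
* the tree water deficit TWD_t = M_t - r_t >= 0 (reversible water-storage
  depletion).

The decomposition is exact: r_t = M_t - TWD_t at every step.  The running
maximum is carried across calendar years within a tree's record — growth
onset is defined against the maximum of the *previous* year — and missing
steps neither reset nor advance it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import RadiusSeries

__all__ = ["ZGDecomposition", "decompose"]


@dataclass
class ZGDecomposition:
    """Running maximum, growth increments, and water deficit of one series."""

    series_id: str
    frame: pd.DataFrame  # index: timestamp; columns: value, run_max, gro_inc, gro_cum, twd

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    def write_csv(self, path: str | Path) -> None:
        out = self.frame.reset_index()[["timestamp", "value", "run_max", "twd", "gro_cum"]]
        out.insert(0, "series_id", self.series_id)
        out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def decompose(s: RadiusSeries) -> ZGDecomposition:
    """Decompose a cleaned, gridded radius series into GRO and TWD.

    Missing values are carried through: the running maximum holds its value
    across gaps, TWD and the growth increment are undefined (NaN / 0) there.
    """
    if len(s) == 0:
        raise ValueError("empty series")
    v = s.values.to_numpy(dtype=float)
    if np.all(np.isnan(v)):
        raise ValueError(f"series {s.series_id!r} has no observations")
    # fmax ignores NaN once a finite value has been seen; leading NaNs stay NaN
    m = np.fmax.accumulate(v)
    twd = m - v
    g = np.diff(m, prepend=m[:1])
    g = np.where(np.isnan(g), 0.0, g)
    first = np.flatnonzero(~np.isnan(m))[0]
    cum = m - m[first]
    frame = pd.DataFrame(
        {"value": v, "run_max": m, "gro_inc": g, "gro_cum": cum, "twd": twd},
        index=s.frame.index,
    )
    return ZGDecomposition(s.series_id, frame)
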