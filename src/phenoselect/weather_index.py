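"""Fast per-station access to daily covariate arrays.

Calibration and prediction repeatedly slice day windows out of station
series; doing that through a DataFrame per candidate parameter vector
would dominate the runtime.  ``WeatherIndex`` stores each station's
covariates as contiguous float arrays keyed by the station's first date,
so a window is an O(1) slice.  Days outside coverage come back as NaN.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .errors import IntegrityError


class WeatherIndex:
    """Per-station contiguous covariate arrays for O(1) window slicing."""

    def __init__(self, weather: pd.DataFrame):
        self._stations: dict[str, tuple[pd.Timestamp, dict[str, np.ndarray]]] = {}
        numeric = [
            c
            for c in weather.columns
            if c not in ("station_id", "date")
            and np.issubdtype(weather[c].dtype, np.number)
        ]
        self.covariates = tuple(numeric)
        for station, g in weather.groupby("station_id", sort=False):
            g = g.sort_values("date")
            dates = pd.DatetimeIndex(g["date"])
            if len(dates) > 1 and not (np.diff(dates.to_numpy()) == np.timedelta64(1, "D")).all():
                raise IntegrityError(f"station {station!r} has date gaps")
            arrays = {c: g[c].to_numpy(dtype=float) for c in numeric}
            self._stations[str(station)] = (dates[0], arrays)

    @property
    def stations(self) -> list[str]:
        return list(self._stations)

    def coverage(self, station_id) -> tuple[pd.Timestamp, pd.Timestamp]:
        start, arrays = self._stations[str(station_id)]
        n = len(next(iter(arrays.values())))
        return start, start + pd.Timedelta(days=n - 1)

    def window(self, station_id, covariate: str, start: date, n_days: int) -> np.ndarray:
        """``n_days`` of ``covariate`` from ``start``; out-of-coverage days are NaN."""
        first, arrays = self._stations[str(station_id)]
        arr = arrays[covariate]
        offset = (pd.Timestamp(start) - first).days
        out = np.full(n_days, np.nan)
        lo = max(offset, 0)
        hi = min(offset + n_days, len(arr))
        if hi > lo:
            out[lo - offset : hi - offset] = arr[lo:hi]
        return out
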