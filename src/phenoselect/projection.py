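"""Application of selected model chains to climate-scenario ensembles.

Per simulation, station and harvest season the four-phase chain is run
from a fixed sowing month-day (default October 30 of the calendar year
preceding the harvest year).  Summaries follow the usual climate-impact
conventions:

* per-station medians of phase dates — expressed as days after emergence
  (DAE) — within named 30-year periods (e.g. reference 1981-2010,
  "2035" = 2020-2049, "2085" = 2070-2099);
* a two-sided ~30-season rolling mean of each simulation's series,
  followed by minima / medians / maxima across stations.

Censored seasons (a phase never reached within the horizon) are excluded
from the medians and counted; the censoring fraction is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .composite import CompositeModel, chain_phases
from .errors import ParameterError, RangeError
from .io_covariates import ScenarioEnsemble
from .weather_index import WeatherIndex

STAGES_OUT = ("emergence", "jointing", "heading", "senescence")


@dataclass(frozen=True)
class ProjectionSummary:
    """Per-station period medians plus the raw per-season predictions."""

    strategy: str
    #: rows: simulation_id, rcm, station_id, harvest_year, and per stage
    #: the predicted date plus days-after-emergence columns `<stage>_dae`
    predictions: pd.DataFrame
    #: rows: period, station_id, stage, median_dae, n, censored_fraction
    period_medians: pd.DataFrame


def _sowing_date(harvest_year: int, sowing_month_day: tuple[int, int]) -> date:
    month, day = sowing_month_day
    # autumn sowing belongs to the preceding calendar year
    year = harvest_year - 1 if month >= 7 else harvest_year
    return date(year, month, day)


def project_periods(
    models: Mapping[str, CompositeModel],
    ensemble: ScenarioEnsemble,
    sowing_month_day: tuple[int, int] = (10, 30),
    periods: Mapping[str, tuple[int, int]] | None = None,
    horizons: Mapping[str, int] | None = None,
    default_horizon: int = 400,
    strategy: str = "opt",
) -> ProjectionSummary:
    """Chained phase predictions over an ensemble with period summaries.

    ``periods`` maps a label to an inclusive harvest-year window; every
    period must lie inside the ensemble's reference + projection
    coverage.
    """
    if periods is None:
        ref = ensemble.reference_window
        periods = {"reference": ref, "2035": (2020, 2049), "2085": (2070, 2099)}
    lo_cov = ensemble.reference_window[0]
    hi_cov = ensemble.projection_window[1]
    for label, (lo, hi) in periods.items():
        if lo < lo_cov or hi > hi_cov:
            raise RangeError(
                f"period {label!r} ({lo}-{hi}) outside ensemble coverage "
                f"({lo_cov}-{hi_cov})"
            )

    rows = []
    for sim in ensemble.simulations:
        wi = WeatherIndex(sim.weather)
        for station in sim.weather["station_id"].unique():
            lo_date, hi_date = wi.coverage(station)
            first_year = lo_date.year + 1
            last_year = hi_date.year
            for year in range(first_year, last_year + 1):
                sowing = _sowing_date(year, sowing_month_day)
                if pd.Timestamp(sowing) < lo_date:
                    continue
                dates = chain_phases(
                    models, wi, station, sowing,
                    horizons=horizons, default_horizon=default_horizon,
                )
                row = {
                    "simulation_id": sim.simulation_id,
                    "rcm": sim.rcm_id,
                    "rcp": sim.rcp_label,
                    "station_id": station,
                    "harvest_year": year,
                    "sowing": sowing,
                }
                emergence = dates["emergence"]
                for stage in STAGES_OUT:
                    d = dates[stage]
                    row[stage] = d
                    if stage != "emergence":
                        row[f"{stage}_dae"] = (
                            float((d - emergence).days)
                            if d is not None and emergence is not None
                            else np.nan
                        )
                rows.append(row)
    predictions = pd.DataFrame(rows)

    summary_rows = []
    for label, (lo, hi) in periods.items():
        in_period = predictions[
            (predictions["harvest_year"] >= lo) & (predictions["harvest_year"] <= hi)
        ]
        for station, g in in_period.groupby("station_id"):
            for stage in ("jointing", "heading", "senescence"):
                vals = g[f"{stage}_dae"]
                n = len(vals)
                censored = float(vals.isna().mean()) if n else float("nan")
                summary_rows.append(
                    {
                        "period": label,
                        "station_id": station,
                        "stage": stage,
                        "median_dae": float(vals.dropna().median()) if n else float("nan"),
                        "n": n,
                        "censored_fraction": censored,
                    }
                )
    return ProjectionSummary(
        strategy=strategy,
        predictions=predictions,
        period_medians=pd.DataFrame(summary_rows),
    )


def rolling_trend(
    predictions: pd.DataFrame,
    value: str = "heading_dae",
    window: int = 30,
    min_half_window: int = 5,
) -> pd.DataFrame:
    """Centered ~``window``-season rolling mean with cross-station envelopes.

    The mean is computed per simulation and station over harvest
    seasons; windows truncate symmetrically near the series ends
    (half-window never below ``min_half_window``).  Returns rows of
    (simulation_id, harvest_year, min, median, max) where the envelope
    statistics run across stations.
    """
    half = window // 2
    out_rows = []
    for sim_id, sim_g in predictions.groupby("simulation_id"):
        smoothed: dict[str, pd.Series] = {}
        for station, g in sim_g.groupby("station_id"):
            g = g.sort_values("harvest_year")
            years = g["harvest_year"].to_numpy()
            vals = g[value].to_numpy(dtype=float)
            n = len(vals)
            if n < window:
                raise ParameterError(
                    f"rolling trend needs >= {window} seasons, got {n} "
                    f"for station {station!r}"
                )
            sm = np.empty(n)
            for i in range(n):
                h = max(min(i, n - 1 - i, half), min_half_window)
                lo, hi = max(0, i - h), min(n, i + h + 1)
                sm[i] = np.nanmean(vals[lo:hi])
            smoothed[station] = pd.Series(sm, index=years)
        mat = pd.DataFrame(smoothed)
        for year, row in mat.iterrows():
            vals = row.dropna()
            if vals.empty:
                continue
            out_rows.append(
                {
                    "simulation_id": sim_id,
                    "harvest_year": int(year),
                    "min": float(vals.min()),
                    "median": float(vals.median()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(out_rows)
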