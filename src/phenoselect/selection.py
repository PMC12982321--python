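"""Three-way model selection under phenology-model and climate-data uncertainty.

``Max_GT`` picks, per complexity level (number of covariates), the model
with the smallest duration RMSE against held-out ground-truth phenology,
and overall the global RMSE minimum — minimizing uncertainty from the
phenology model itself.

``Max_CS`` takes only those per-complexity winners and compares, over a
reference period in which both observed weather and scenario simulations
exist, the durations each model predicts from a *fixed* phase start
(median observed day-of-year) under observations versus under every
simulation.  Per-simulation RMSEs are averaged within each regional
climate model (RCM) and then across RCMs, so over-represented RCMs do
not bias the score — minimizing uncertainty from the scenario data.

``Opt`` ("Goldilocks") takes, within the closed complexity interval
spanned by the two winners, the complexity with the smallest mean of the
two RMSEs.

All ties resolve toward fewer covariates, then the lexicographically
smaller subset id — selection is a pure, deterministic function of its
inputs.
"""

from __future__ import annotations

import contextlib
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composite import CompositeModel, evaluate_model, predict_phase_end
from .drc import PHASE_BOUNDS
from .errors import ParameterError, SelectionError
from .io_covariates import PhenologyEnvironment, ScenarioEnsemble
from .weather_index import WeatherIndex


@dataclass(frozen=True)
class ProfileEntry:
    model_id: str
    rmse: float
    mae: float = float("nan")
    pearson_r: float = float("nan")


@dataclass(frozen=True)
class ComplexityProfile:
    """Best model and its score per complexity level, for one phase."""

    phase: str
    metric: str  # "rmse_gt" | "rmse_cs"
    entries: Mapping[int, ProfileEntry]

    def rmse(self, complexity: int) -> float:
        return self.entries[complexity].rmse

    @property
    def complexities(self) -> list[int]:
        return sorted(self.entries)


@dataclass(frozen=True)
class SelectionOutcome:
    strategy: str  # "max_gt" | "max_cs" | "opt"
    phase: str
    model_id: str
    complexity: int
    trace: Mapping[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "phase": self.phase,
            "model_id": self.model_id,
            "complexity": self.complexity,
            "trace": {int(k): float(v) for k, v in self.trace.items()},
        }


def _argmin_entry(scores: Mapping[int, tuple[float, str]]) -> tuple[int, str]:
    """Smallest score; ties toward fewer covariates then lexicographic id."""
    best = min(
        scores.items(), key=lambda kv: (kv[1][0], kv[0], kv[1][1])
    )
    return best[0], best[1][1]


# ---------------------------------------------------------------------------
# Max_GT
# ---------------------------------------------------------------------------

def validation_durations(
    model: CompositeModel,
    environments: Sequence[PhenologyEnvironment],
    weather: WeatherIndex,
    horizon: int,
) -> tuple[list[float | None], list[float]]:
    """Predicted and observed durations on a set of environments.

    Each prediction starts at the environment's *observed* phase start.
    """
    start_name, end_name = PHASE_BOUNDS[model.phase]
    pred: list[float | None] = []
    obs: list[float] = []
    for env in environments:
        start = getattr(env, start_name)
        end = getattr(env, end_name)
        if start is None or end is None:
            continue
        _, dur = predict_phase_end(model, weather, env.station_id, start, horizon)
        pred.append(None if np.isnan(dur) else dur)
        obs.append(float((end - start).days))
    return pred, obs


def select_max_gt(
    models: Sequence[CompositeModel],
    validation_envs: Sequence[PhenologyEnvironment],
    weather: WeatherIndex,
    horizon: int = 400,
) -> tuple[ComplexityProfile, SelectionOutcome]:
    """Ground-truth selection: RMSE-minimal model per complexity and overall."""
    if not validation_envs:
        raise SelectionError("empty validation set")
    if not models:
        raise SelectionError("no fitted models")
    phase = models[0].phase
    per_complexity: dict[int, dict] = {}
    for model in models:
        pred, obs = validation_durations(model, validation_envs, weather, horizon)
        metrics = evaluate_model(pred, obs)
        k = model.complexity
        entry = per_complexity.get(k)
        key = (metrics["rmse"], model.model_id)
        if entry is None or key < (entry["rmse"], entry["model_id"]):
            per_complexity[k] = {
                "model_id": model.model_id,
                "rmse": metrics["rmse"],
                "mae": metrics["mae"],
                "pearson_r": metrics["pearson_r"],
            }
    profile = ComplexityProfile(
        phase=phase,
        metric="rmse_gt",
        entries={
            k: ProfileEntry(v["model_id"], v["rmse"], v["mae"], v["pearson_r"])
            for k, v in per_complexity.items()
        },
    )
    k_best, id_best = _argmin_entry(
        {k: (v["rmse"], v["model_id"]) for k, v in per_complexity.items()}
    )
    outcome = SelectionOutcome(
        strategy="max_gt",
        phase=phase,
        model_id=id_best,
        complexity=k_best,
        trace={k: v["rmse"] for k, v in per_complexity.items()},
    )
    return profile, outcome


# ---------------------------------------------------------------------------
# Max_CS
# ---------------------------------------------------------------------------

def phase_start_date(harvest_year: int, start_doy: int) -> date:
    """Fixed phase start for a harvest season.

    A day-of-year of 182 (Jul 1) or later belongs to the calendar year
    preceding the harvest year (autumn-sown phases of a winter crop).
    """
    year = harvest_year - 1 if start_doy >= 182 else harvest_year
    return date(year, 1, 1) + timedelta(days=start_doy - 1)


def median_phase_starts(
    environments: Sequence[PhenologyEnvironment],
) -> dict[str, int]:
    """Median observed start day-of-year per phase (the fixed-start table)."""
    out: dict[str, int] = {}
    for phase, (start_name, _) in PHASE_BOUNDS.items():
        doys = []
        for env in environments:
            d = getattr(env, start_name)
            if d is not None:
                doys.append(d.timetuple().tm_yday)
        if doys:
            out[phase] = int(round(float(np.median(doys))))
    return out


def rcm_averaged_rmse(
    per_sim_rmse: Sequence[float],
    per_sim_rcm: Sequence[str],
    rcm_average: bool = True,
) -> float:
    """Two-stage mean: within each RCM first, then across RCMs.

    Keeps over-represented RCMs from dominating the score; with
    ``rcm_average=False`` simulations are averaged uniformly instead.
    """
    if not rcm_average:
        return float(np.mean(per_sim_rmse))
    by_rcm: dict[str, list[float]] = {}
    for rcm, v in zip(per_sim_rcm, per_sim_rmse):
        by_rcm.setdefault(rcm, []).append(v)
    return float(np.mean([np.mean(v) for v in by_rcm.values()]))


def _fixed_start_durations(
    model: CompositeModel,
    weather: WeatherIndex,
    stations: Sequence[str],
    years: Sequence[int],
    start_doy: int,
    horizon: int,
) -> np.ndarray:
    out = np.full((len(stations), len(years)), np.nan)
    for i, station in enumerate(stations):
        for j, year in enumerate(years):
            start = phase_start_date(year, start_doy)
            try:
                _, dur = predict_phase_end(model, weather, station, start, horizon)
            except KeyError:
                continue
            out[i, j] = dur
    return out


def select_max_cs(
    best_per_complexity: Mapping[int, CompositeModel],
    obs_weather: WeatherIndex,
    ensemble: ScenarioEnsemble,
    fixed_phase_starts: Mapping[str, int],
    horizon: int = 400,
    rcm_average: bool = True,
    per_station: bool = False,
    average_predictions_first: bool = False,
) -> tuple[ComplexityProfile, SelectionOutcome]:
    """Climate-scenario selection over the reference period.

    For every complexity level, phase durations are predicted from the
    fixed start day-of-year for each station x harvest year of the
    reference window, once under observed weather and once under each
    simulation; the pooled per-simulation RMSE is averaged within RCMs
    and then across RCMs.  Switches for the alternative readings:
    ``rcm_average=False`` averages simulations uniformly;
    ``per_station=True`` computes the RMSE per station and averages
    those; ``average_predictions_first=True`` averages the simulated
    durations across the ensemble (within then across RCMs) before a
    single comparison against the observation-driven durations.
    """
    if not best_per_complexity:
        raise SelectionError("no per-complexity models supplied")
    phase = next(iter(best_per_complexity.values())).phase
    start_doy = fixed_phase_starts[phase]
    ref_lo, ref_hi = ensemble.reference_window
    years = list(range(ref_lo, ref_hi + 1))
    stations = ensemble.stations
    obs_years = [
        y for y in years
        if all(
            _covers(obs_weather, s, phase_start_date(y, start_doy), horizon)
            for s in stations
        )
    ]
    if not obs_years:
        raise SelectionError("no reference-window overlap with observed weather")

    sim_indexes = [
        (sim.rcm_id, WeatherIndex(sim.weather)) for sim in ensemble.simulations
    ]
    scores: dict[int, tuple[float, str]] = {}
    for k in sorted(best_per_complexity):
        model = best_per_complexity[k]
        obs_dur = _fixed_start_durations(
            model, obs_weather, stations, obs_years, start_doy, horizon
        )
        sim_durations = [
            (rcm, _fixed_start_durations(model, wi, stations, obs_years,
                                         start_doy, horizon))
            for rcm, wi in sim_indexes
        ]
        if average_predictions_first:
            by_rcm: dict[str, list[np.ndarray]] = {}
            for rcm, dur in sim_durations:
                by_rcm.setdefault(rcm, []).append(dur)
            with warnings_suppressed():
                rcm_means = [np.nanmean(np.stack(v), axis=0) for v in by_rcm.values()]
                mean_dur = np.nanmean(np.stack(rcm_means), axis=0)
            diff = mean_dur - obs_dur
            rmse_cs = _pooled_or_per_station_rmse(diff, per_station)
            if rmse_cs is None:
                raise SelectionError(
                    f"no valid simulation comparisons at complexity {k}"
                )
        else:
            per_sim_rmse: list[float] = []
            per_sim_rcm: list[str] = []
            for rcm, sim_dur in sim_durations:
                rmse = _pooled_or_per_station_rmse(sim_dur - obs_dur, per_station)
                if rmse is None:
                    continue
                per_sim_rmse.append(rmse)
                per_sim_rcm.append(rcm)
            if not per_sim_rmse:
                raise SelectionError(
                    f"no valid simulation comparisons at complexity {k}"
                )
            rmse_cs = rcm_averaged_rmse(per_sim_rmse, per_sim_rcm, rcm_average)
        scores[k] = (rmse_cs, model.model_id)

    profile = ComplexityProfile(
        phase=phase,
        metric="rmse_cs",
        entries={k: ProfileEntry(mid, r) for k, (r, mid) in scores.items()},
    )
    k_best, id_best = _argmin_entry(scores)
    outcome = SelectionOutcome(
        strategy="max_cs",
        phase=phase,
        model_id=id_best,
        complexity=k_best,
        trace={k: r for k, (r, _) in scores.items()},
    )
    return profile, outcome


def _pooled_or_per_station_rmse(diff: np.ndarray, per_station: bool) -> float | None:
    """RMSE of a (station, year) difference matrix; None if all censored."""
    valid = ~np.isnan(diff)
    if not valid.any():
        return None
    if not per_station:
        return float(np.sqrt(np.mean(diff[valid] ** 2)))
    rmses = []
    for row in diff:
        v = row[~np.isnan(row)]
        if len(v):
            rmses.append(np.sqrt(np.mean(v**2)))
    return float(np.mean(rmses))


@contextlib.contextmanager
def warnings_suppressed():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def _covers(weather: WeatherIndex, station, start: date, horizon: int) -> bool:
    try:
        lo, hi = weather.coverage(station)
    except KeyError:
        return False
    return pd.Timestamp(start) >= lo and pd.Timestamp(start) + pd.Timedelta(
        days=horizon
    ) <= hi


# ---------------------------------------------------------------------------
# Opt
# ---------------------------------------------------------------------------

def select_opt(
    profile_gt: ComplexityProfile,
    outcome_gt: SelectionOutcome,
    profile_cs: ComplexityProfile,
    outcome_cs: SelectionOutcome,
) -> SelectionOutcome:
    """Smallest mean of the two RMSEs within the winners' complexity interval."""
    shared = sorted(set(profile_gt.entries) & set(profile_cs.entries))
    if not shared:
        raise SelectionError("profiles share no complexity level")
    means = {
        k: (profile_gt.rmse(k) + profile_cs.rmse(k)) / 2.0 for k in shared
    }
    k_lo = min(outcome_gt.complexity, outcome_cs.complexity)
    k_hi = max(outcome_gt.complexity, outcome_cs.complexity)
    window = {k: v for k, v in means.items() if k_lo <= k <= k_hi}
    if not window:
        raise SelectionError("winners' complexity interval not covered by profiles")
    k_best, _ = _argmin_entry(
        {k: (v, profile_gt.entries[k].model_id) for k, v in window.items()}
    )
    assert k_lo <= k_best <= k_hi
    return SelectionOutcome(
        strategy="opt",
        phase=profile_gt.phase,
        model_id=profile_gt.entries[k_best].model_id,
        complexity=k_best,
        trace=means,
    )


def relative_uncertainty(rmse: float, duration_sd: float) -> float:
    """Skill score standardized by the phase-duration standard deviation."""
    if not duration_sd > 0:
        raise ParameterError("duration SD must be positive")
    return float(rmse) / float(duration_sd)
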