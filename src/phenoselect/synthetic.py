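"""Synthetic weather, phenology and scenario-ensemble generation.

The generator emulates the statistical structure of multi-station daily
weather observations for a temperate winter-wheat region, phenology
observations produced by a *known* additive dose model, and a
bias-adjusted climate-model ensemble that agrees with the observations
in a reference period up to controllable per-covariate bias and noise,
plus an optional warming trend beyond it.  Because the generating truth
is known, parameter recovery and model-selection behaviour become
directly testable.

Weather per station: a sinusoidal annual cycle plus AR(1) anomalies for
mean temperature, with tasmin/tasmax derived from positive spreads so
the ordering invariant holds by construction; relative humidity clipped
to [20, 100]; precipitation from a zero-inflated gamma; radiation
seasonal and non-negative.

Phenology per station x harvest year: from a fixed sowing date, each
phase ends on the first day its true beta-weighted accumulated dose
reaches the true required dose, plus rounded Gaussian observation noise.

All randomness flows from the mandatory seed; regenerating a bundle
from its provenance reproduces it bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .drc import DRCSpec, PHASES, eval_drc_array
from .errors import ConfigurationError
from .io_covariates import (
    PhenologyEnvironment,
    ScenarioEnsemble,
    Simulation,
    validate_weather,
)
from .weather_index import WeatherIndex


@dataclass(frozen=True)
class CovariateCycle:
    """Annual sinusoid + AR(1) anomaly parameters for one covariate."""

    mean: float
    amplitude: float
    peak_doy: int = 200  # late July
    ar1: float = 0.7
    noise_sd: float = 2.0


@dataclass(frozen=True)
class WeatherConfig:
    """Defaults emulate a temperate central-European station network."""

    tas: CovariateCycle = CovariateCycle(mean=9.0, amplitude=9.0, peak_doy=200,
                                         ar1=0.7, noise_sd=2.0)
    RH: CovariateCycle = CovariateCycle(mean=75.0, amplitude=-10.0, peak_doy=200,
                                        ar1=0.5, noise_sd=5.0)
    GR: CovariateCycle = CovariateCycle(mean=1100.0, amplitude=900.0, peak_doy=172,
                                        ar1=0.4, noise_sd=150.0)
    tasmin_spread_mean: float = 4.5
    tasmax_spread_mean: float = 5.0
    spread_sd: float = 1.2
    pr_wet_prob: float = 0.5
    pr_shape: float = 0.8
    pr_scale: float = 5.0
    station_mean_sd: float = 0.8  # between-station offset of the tas mean

    def __post_init__(self):
        if self.tasmin_spread_mean <= 0 or self.tasmax_spread_mean <= 0:
            raise ConfigurationError("temperature spreads must be positive")


@dataclass(frozen=True)
class PhaseTruth:
    """True generating model of one phase: weighted DRC doses + requirement."""

    drcs: Mapping[str, DRCSpec]
    weights: Mapping[str, float]
    required_dose: float


def default_truth() -> dict[str, PhaseTruth]:
    """Single-covariate cardinal-temperature truth per phase.

    The (0, 25, 35) deg C cardinals are plausible wheat values used as
    test constants, not field estimates; required doses are set so an
    October 30 sowing gives roughly 10-35 days to emergence, jointing in
    April, heading in early June and senescence in late July under the
    default weather climatology.
    """

    def we(phase, base, opt, mx):
        return DRCSpec("wang_engel", "tas", phase,
                       {"psi_base": base, "psi_opt": opt, "psi_max": mx, "r": 1.0})

    return {
        "sowing-emergence": PhaseTruth(
            {"tas": we("sowing-emergence", 0.0, 25.0, 35.0)}, {"tas": 1.0}, 1.5
        ),
        "emergence-jointing": PhaseTruth(
            {"tas": we("emergence-jointing", 0.0, 25.0, 35.0)}, {"tas": 1.0}, 6.0
        ),
        "jointing-heading": PhaseTruth(
            {"tas": we("jointing-heading", 0.0, 25.0, 35.0)}, {"tas": 1.0}, 23.0
        ),
        "heading-senescence": PhaseTruth(
            {"tas": we("heading-senescence", 0.0, 25.0, 35.0)}, {"tas": 1.0}, 32.0
        ),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    n_simulations: int = 6
    rcm_labels: tuple[str, ...] = ("RCM-A", "RCM-B", "RCM-C")
    gcm_labels: tuple[str, ...] = ("GCM-1", "GCM-2")
    rcp_label: str = "RCP8.5"
    bias: Mapping[str, float] = field(default_factory=dict)
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    ar1: float = 0.5
    trend_per_year: float = 0.0  # deg C / year added to temperatures past the reference
    projection_end_year: int | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    n_stations: int = 5
    n_years: int = 20
    start_year: int = 1991
    seed: int = 0
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    truth: Mapping[str, PhaseTruth] = field(default_factory=default_truth)
    duration_noise_sd: float = 2.0
    sowing_month_day: tuple[int, int] = (10, 30)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)


@dataclass(frozen=True)
class GroundTruthBundle:
    weather: pd.DataFrame
    environments: list[PhenologyEnvironment]
    truth: Mapping[str, PhaseTruth]
    ensemble: ScenarioEnsemble | None
    config: SyntheticConfig
    n_skipped: int = 0


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def _seasonal(cycle: CovariateCycle, doy: np.ndarray, rng: np.random.Generator,
              offset: float = 0.0) -> np.ndarray:
    base = cycle.mean + offset + cycle.amplitude * np.cos(
        2.0 * np.pi * (doy - cycle.peak_doy) / 365.25
    )
    n = len(doy)
    if cycle.noise_sd > 0:
        anom = _ar1(rng.normal(0.0, cycle.noise_sd, size=n), cycle.ar1)
    else:
        anom = np.zeros(n)
    return base + anom


def _ar1(innovations: np.ndarray, phi: float) -> np.ndarray:
    """Stationary-variance AR(1) path driven by the given innovations."""
    from scipy.signal import lfilter

    scale = np.sqrt(max(1.0 - phi**2, 1e-12))
    return lfilter([scale], [1.0, -phi], innovations)


def gen_weather(config: SyntheticConfig) -> pd.DataFrame:
    """Daily weather for all stations over the configured years."""
    wc = config.weather
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dates = pd.date_range(
        start=f"{config.start_year}-01-01",
        end=f"{config.start_year + config.n_years - 1}-12-31",
        freq="D",
    )
    doy = dates.dayofyear.to_numpy().astype(float)
    frames = []
    for s in range(config.n_stations):
        station = f"ST{s + 1:03d}"
        offset = float(rng.normal(0.0, wc.station_mean_sd))
        tas = _seasonal(wc.tas, doy, rng, offset=offset)
        lo_spread = np.maximum(
            rng.normal(wc.tasmin_spread_mean, wc.spread_sd, len(dates)), 0.1
        )
        hi_spread = np.maximum(
            rng.normal(wc.tasmax_spread_mean, wc.spread_sd, len(dates)), 0.1
        )
        rh = np.clip(_seasonal(wc.RH, doy, rng), 20.0, 100.0)
        gr = np.maximum(_seasonal(wc.GR, doy, rng), 0.0)
        wet = rng.random(len(dates)) < wc.pr_wet_prob
        pr = np.where(wet, rng.gamma(wc.pr_shape, wc.pr_scale, len(dates)), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "station_id": station,
                    "date": dates,
                    "tasmin": tas - lo_spread,
                    "tas": tas,
                    "tasmax": tas + hi_spread,
                    "RH": rh,
                    "pr": pr,
                    "GR": gr,
                }
            )
        )
    return validate_weather(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

def _true_crossing_day(
    truth: PhaseTruth, weather: WeatherIndex, station, start: date, horizon: int = 400
) -> int | None:
    dose = np.zeros(horizon)
    for cov, spec in truth.drcs.items():
        x = weather.window(station, cov, start, horizon)
        resp = eval_drc_array(spec.family, spec.params, x)
        dose += truth.weights[cov] * np.where(np.isnan(resp), 0.0, resp)
    cum = np.cumsum(dose)
    reached = cum >= truth.required_dose
    if not reached.any():
        return None
    return int(np.argmax(reached)) + 1  # duration in whole days


def gen_phenology(
    weather: pd.DataFrame,
    truth: Mapping[str, PhaseTruth],
    noise_sd: float,
    seed: int,
    sowing_month_day: tuple[int, int] = (10, 30),
) -> tuple[list[PhenologyEnvironment], int]:
    """Forward-simulate phase-boundary observations from the true dose model.

    Returns (environments, number skipped because a phase never reached
    its required dose within the horizon or fell outside coverage).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    wi = WeatherIndex(weather)
    month, day = sowing_month_day
    envs: list[PhenologyEnvironment] = []
    n_skipped = 0
    for station in wi.stations:
        lo, hi = wi.coverage(station)
        for harvest_year in range(lo.year + 1, hi.year + 1):
            sow_year = harvest_year - 1 if month >= 7 else harvest_year
            sowing = date(sow_year, month, day)
            if pd.Timestamp(sowing) < lo:
                continue
            stages = {"sowing": sowing}
            start = sowing
            ok = True
            for phase in PHASES:
                dur = _true_crossing_day(truth[phase], wi, station, start)
                if dur is None:
                    ok = False
                    break
                if noise_sd > 0:
                    dur = max(dur + int(round(rng.normal(0.0, noise_sd))), 1)
                end = start + timedelta(days=dur)
                if pd.Timestamp(end) > hi:
                    ok = False
                    break
                stages[phase.split("-")[1]] = end
                start = end
            if not ok:
                n_skipped += 1
                continue
            envs.append(
                PhenologyEnvironment(
                    station_id=station, harvest_year=harvest_year, **stages
                )
            )
    return envs, n_skipped


# ---------------------------------------------------------------------------
# scenario ensembles
# ---------------------------------------------------------------------------

_TEMP_COLS = ("tasmin", "tas", "tasmax")


def _extend_weather(weather: pd.DataFrame, end_year: int) -> pd.DataFrame:
    """Recycle observed years cyclically (by month-day) out to ``end_year``."""
    frames = [weather]
    obs_years = pd.to_datetime(weather["date"]).dt.year
    y0, y1 = int(obs_years.min()), int(obs_years.max())
    n_cycle = y1 - y0 + 1
    for station, g in weather.groupby("station_id", sort=False):
        g = g.copy()
        g["md"] = pd.to_datetime(g["date"]).dt.strftime("%m-%d")
        g["year"] = pd.to_datetime(g["date"]).dt.year
        for year in range(y1 + 1, end_year + 1):
            src_year = y0 + (year - y0) % n_cycle
            src = g[g["year"] == src_year].set_index("md")
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            md = dates.strftime("%m-%d")
            # Feb 29 of a target leap year borrows Feb 28 when absent
            md = pd.Index([m if m in src.index else "02-28" for m in md])
            block = src.loc[md].reset_index(drop=True)
            block["date"] = dates
            frames.append(block[weather.columns])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["station_id", "date"], kind="stable").reset_index(drop=True)


def gen_scenario_ensemble(
    weather: pd.DataFrame,
    config: SyntheticConfig,
) -> ScenarioEnsemble:
    """Simulations = observations + per-covariate bias/noise + trend.

    Within the reference window (the observed years) each simulation
    equals the observations up to the configured additive bias and AR(1)
    noise; beyond it the observed seasonal structure is recycled and a
    linear warming trend (deg C/year, temperatures only) is added.
    Temperature ordering is preserved by perturbing ``tas`` and carrying
    the observed spreads.
    """
    sc = config.scenario
    years = pd.to_datetime(weather["date"]).dt.year
    ref_lo, ref_hi = int(years.min()), int(years.max())
    end_year = sc.projection_end_year or ref_hi
    if end_year < ref_hi:
        raise ConfigurationError(
            f"projection horizon {end_year} precedes reference end {ref_hi}"
        )
    base = _extend_weather(weather, end_year) if end_year > ref_hi else weather.copy()
    base_years = pd.to_datetime(base["date"]).dt.year.to_numpy()
    years_past_ref = np.maximum(base_years - ref_hi, 0).astype(float)

    sims = []
    for i in range(sc.n_simulations):
        sim_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 3, i + 1])
        )
        df = base.copy()
        spreads_lo = df["tas"] - df["tasmin"]
        spreads_hi = df["tasmax"] - df["tas"]
        for cov in ("tas", "RH", "pr", "GR"):
            bias = float(sc.bias.get(cov, 0.0))
            sd = float(sc.noise_sd.get(cov, 0.0))
            noise = (
                _ar1(sim_rng.normal(0.0, sd, len(df)), sc.ar1)
                if sd > 0
                else 0.0
            )
            df[cov] = df[cov] + bias + noise
        if sc.trend_per_year != 0.0:
            df["tas"] = df["tas"] + sc.trend_per_year * years_past_ref
        df["tasmin"] = df["tas"] - spreads_lo
        df["tasmax"] = df["tas"] + spreads_hi
        df["pr"] = df["pr"].clip(lower=0.0)
        df["RH"] = df["RH"].clip(0.0, 100.0)
        df["GR"] = df["GR"].clip(lower=0.0)
        sims.append(
            Simulation(
                simulation_id=f"SIM{i + 1:03d}",
                rcm_id=sc.rcm_labels[i % len(sc.rcm_labels)],
                gcm_id=sc.gcm_labels[i % len(sc.gcm_labels)],
                rcp_label=sc.rcp_label,
                weather=df,
            )
        )
    return ScenarioEnsemble(
        simulations=sims,
        reference_window=(ref_lo, ref_hi),
        projection_window=(ref_hi, end_year),
    )


def three_covariate_truth() -> dict[str, PhaseTruth]:
    """A truth whose spring phase is driven by three covariates.

    jointing-heading accumulates a weighted sum of temperature
    (cardinal response), radiation (cardinal response on GR) and a
    broken-stick response to relative humidity; the other phases remain
    temperature-driven.  Used to exercise multi-covariate composite
    fitting and model selection against a known generating complexity.
    """
    truth = default_truth()
    phase = "jointing-heading"
    drcs = {
        "tas": truth[phase].drcs["tas"],
        "GR": DRCSpec("wang_engel", "GR", phase,
                      {"psi_base": 0.0, "psi_opt": 2000.0, "psi_max": 4000.0,
                       "r": 1.0}),
        "RH": DRCSpec("broken_stick", "RH", phase,
                      {"psi_base": 40.0, "slope": 0.02}),
    }
    weights = {"tas": 0.5, "GR": 0.3, "RH": 0.2}
    out = dict(truth)
    out[phase] = PhaseTruth(drcs, weights, 28.0)
    return out


def recovery_config(seed: int, n_stations: int = 25, n_years: int = 21) -> SyntheticConfig:
    """Study conditions for cardinal-parameter recovery experiments.

    ~500 environments (25 stations x 20 harvest years) with duration
    observation noise of 2 days.  The climatology is a warm-summer
    variant (tas mean 10 deg C, amplitude 11, daily anomaly SD 3) so the
    phase windows actually sample the full cardinal range: a response
    optimum can only be located where the covariate occasionally reaches
    and exceeds it.  The optimum is therefore assessed on the summer
    phase (heading-senescence) and the base temperature on the spring
    phase (jointing-heading), each in the regime where the data carry
    information about it.
    """
    return SyntheticConfig(
        n_stations=n_stations,
        n_years=n_years,
        seed=seed,
        duration_noise_sd=2.0,
        weather=WeatherConfig(
            tas=CovariateCycle(mean=10.0, amplitude=11.0, peak_doy=200,
                               ar1=0.7, noise_sd=3.0)
        ),
    )


def generate_bundle(config: SyntheticConfig, with_ensemble: bool = True) -> GroundTruthBundle:
    """Weather + phenology (+ scenario ensemble) from one seeded config."""
    weather = gen_weather(config)
    envs, n_skipped = gen_phenology(
        weather, config.truth, config.duration_noise_sd, config.seed,
        sowing_month_day=config.sowing_month_day,
    )
    ensemble = gen_scenario_ensemble(weather, config) if with_ensemble else None
    return GroundTruthBundle(
        weather=weather,
        environments=envs,
        truth=config.truth,
        ensemble=ensemble,
        config=config,
        n_skipped=n_skipped,
    )
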