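"""Weather / phenology I/O, derived covariates, and the train/validation split.

File formats are deliberately plain: comma-delimited UTF-8 CSV with a
header and ISO-8601 dates.  Scenario ensembles are a directory of such
CSVs plus a YAML manifest mapping each file to its simulation tag
(simulation id, RCM, GCM, RCP).  Fitted models are serialized to JSON
with a format-version field.

Derived covariates:

* VPD (vapor pressure deficit, hPa) from temperature and relative
  humidity via the Magnus saturation-pressure formula.
* SPI (standardized precipitation index, unitless) from daily
  precipitation: trailing 30-day sums, a gamma distribution with a point
  mass at zero fitted per calendar month pooled across years, then a
  probit transform.  The result is approximately standard normal over
  the fitting sample.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import (
    DegenerateDataError,
    FormatError,
    IntegrityError,
    ParameterError,
    RangeError,
)

logger = logging.getLogger(__name__)

RAW_COVARIATES = ("tasmin", "tas", "tasmax", "RH", "pr", "GR")
#: the seven covariates entering the composite models
MODEL_COVARIATES = ("tasmin", "tas", "tasmax", "RH", "SPI", "VPD", "GR")
WEATHER_COLUMNS = ("station_id", "date") + RAW_COVARIATES
STAGES = ("sowing", "emergence", "jointing", "heading", "senescence")

MODEL_FORMAT_VERSION = 1

# Magnus saturation vapor pressure constants (hPa, T in deg C)
_MAGNUS_A = 6.1078
_MAGNUS_B = 17.27
_MAGNUS_C = 237.3


@dataclass(frozen=True)
class PhenologyEnvironment:
    """One station x season with its observed phase-boundary dates."""

    station_id: str
    harvest_year: int
    sowing: date | None = None
    emergence: date | None = None
    jointing: date | None = None
    heading: date | None = None
    senescence: date | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.station_id, self.harvest_year)

    def stage_dates(self) -> dict[str, date | None]:
        return {s: getattr(self, s) for s in STAGES}

    def is_ordered(self) -> bool:
        present = [d for d in (self.stage_dates()[s] for s in STAGES) if d is not None]
        return all(a < b for a, b in zip(present, present[1:]))


@dataclass(frozen=True)
class Simulation:
    """One climate-model run of a scenario ensemble."""

    simulation_id: str
    rcm_id: str
    gcm_id: str
    rcp_label: str
    weather: pd.DataFrame


@dataclass(frozen=True)
class ScenarioEnsemble:
    """A set of RCM/GCM/RCP-tagged simulations over shared stations/windows."""

    simulations: Sequence[Simulation]
    reference_window: tuple[int, int]
    projection_window: tuple[int, int]

    @property
    def stations(self) -> list[str]:
        out: list[str] = []
        for sim in self.simulations:
            for s in sim.weather["station_id"].unique():
                if s not in out:
                    out.append(s)
        return out


# ---------------------------------------------------------------------------
# weather tables
# ---------------------------------------------------------------------------

def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Check the daily-weather invariants; return the table date-sorted.

    Raises on missing columns, duplicated or gappy dates, temperature
    ordering violations, relative humidity outside [0, 100] and negative
    precipitation/radiation.
    """
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"weather table missing column(s): {', '.join(missing)}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["station_id", "date"], kind="stable").reset_index(drop=True)

    dup = df.duplicated(["station_id", "date"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IntegrityError(
            f"duplicate (station, date) row: ({row['station_id']}, "
            f"{row['date'].date()})"
        )
    for station, g in df.groupby("station_id", sort=False):
        deltas = g["date"].diff().dropna().dt.days
        if (deltas != 1).any():
            bad = g["date"].iloc[int(np.argmax((deltas != 1).to_numpy())) + 1]
            raise IntegrityError(
                f"station {station!r}: dates not gap-free around {bad.date()}"
            )
    bad = ~((df["tasmin"] <= df["tas"]) & (df["tas"] <= df["tasmax"]))
    if bad.any():
        row = df[bad].iloc[0]
        raise IntegrityError(
            "tasmin <= tas <= tasmax violated at "
            f"({row['station_id']}, {row['date'].date()})"
        )
    if ((df["RH"] < 0) | (df["RH"] > 100)).any():
        raise RangeError("RH outside [0, 100]")
    if (df["pr"] < 0).any():
        raise RangeError("negative precipitation")
    if (df["GR"] < 0).any():
        raise RangeError("negative global radiation")
    return df


def read_weather(path) -> pd.DataFrame:
    """Read and validate a station weather CSV."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse weather file {path}: {exc}") from exc
    return validate_weather(df)


def write_weather(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def interpolate_gaps(series: pd.Series, max_gap: int = 3) -> pd.Series:
    """Linearly fill NaN runs of at most ``max_gap`` days; longer runs raise."""
    isna = series.isna()
    if not isna.any():
        return series
    run = 0
    for v in isna:
        run = run + 1 if v else 0
        if run > max_gap:
            raise IntegrityError(f"gap longer than {max_gap} days")
    return series.interpolate(method="linear", limit_area="inside")


# ---------------------------------------------------------------------------
# phenology tables
# ---------------------------------------------------------------------------

def read_phenology(path) -> list[PhenologyEnvironment]:
    """Read phenology observations; mis-ordered records are dropped with a log."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"phenology file {path} is empty", stacklevel=2)
        return []
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse phenology file {path}: {exc}") from exc
    required = ["station_id", "harvest_year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"phenology table missing column(s): {', '.join(missing)}")
    if df.empty:
        warnings.warn(f"phenology file {path} has no records", stacklevel=2)
        return []

    envs: list[PhenologyEnvironment] = []
    n_dropped = 0
    for _, row in df.iterrows():
        dates: dict[str, date | None] = {}
        for stage in STAGES:
            raw = row.get(stage)
            if pd.isna(raw) if not isinstance(raw, str) else raw.strip() == "":
                dates[stage] = None
                continue
            try:
                dates[stage] = pd.Timestamp(raw).date()
            except (ValueError, TypeError) as exc:
                raise FormatError(
                    f"unparseable {stage} date {raw!r} for station "
                    f"{row['station_id']!r}"
                ) from exc
        env = PhenologyEnvironment(
            station_id=str(row["station_id"]),
            harvest_year=int(row["harvest_year"]),
            **dates,
        )
        if not env.is_ordered():
            n_dropped += 1
            continue
        envs.append(env)
    if n_dropped:
        logger.warning("dropped %d phenology record(s) with mis-ordered dates", n_dropped)
        warnings.warn(
            f"dropped {n_dropped} phenology record(s) with mis-ordered dates",
            stacklevel=2,
        )
    return envs


def write_phenology(envs: Iterable[PhenologyEnvironment], path) -> None:
    rows = []
    for e in envs:
        row = {"station_id": e.station_id, "harvest_year": e.harvest_year}
        for s in STAGES:
            d = getattr(e, s)
            row[s] = d.isoformat() if d is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# derived covariates
# ---------------------------------------------------------------------------

def magnus_saturation_pressure(tas) -> np.ndarray | float:
    """Magnus saturation vapor pressure e_s(T) in hPa for T in deg C."""
    t = np.asarray(tas, dtype=float)
    es = _MAGNUS_A * np.exp(_MAGNUS_B * t / (t + _MAGNUS_C))
    return float(es) if np.isscalar(tas) else es


def compute_vpd(tas, RH) -> np.ndarray | float:
    """Vapor pressure deficit e_s(tas) * (1 - RH/100), in hPa.

    Zero at saturation (RH = 100) and equal to e_s at RH = 0; monotone
    decreasing in RH and increasing in temperature below saturation.
    """
    rh = np.asarray(RH, dtype=float)
    valid = np.isnan(rh) | ((rh >= 0.0) & (rh <= 100.0))
    if not np.all(valid):
        raise RangeError("RH outside [0, 100]")
    vpd = magnus_saturation_pressure(np.asarray(tas, dtype=float)) * (1.0 - rh / 100.0)
    return float(vpd) if np.isscalar(RH) and np.isscalar(tas) else vpd


@dataclass(frozen=True)
class SPIModel:
    """Per-calendar-month gamma-with-zero-mass fits for windowed rain sums."""

    window: int
    # month -> (zero fraction q, gamma shape, gamma scale)
    month_params: Mapping[int, tuple[float, float, float]]

    def transform(self, sums: pd.Series) -> pd.Series:
        months = sums.index.month
        out = np.full(len(sums), np.nan)
        vals = sums.to_numpy(dtype=float)
        for month, (q, shape, scale) in self.month_params.items():
            m = (months == month) & ~np.isnan(vals)
            if not m.any():
                continue
            x = vals[m]
            g = stats.gamma.cdf(x, shape, loc=0.0, scale=scale)
            p = np.where(x <= 0.0, q, q + (1.0 - q) * g)
            p = np.clip(p, 1e-9, 1.0 - 1e-9)
            out[np.flatnonzero(m)] = stats.norm.ppf(p)
        return pd.Series(out, index=sums.index)


def fit_spi(pr: pd.Series, window: int = 30) -> SPIModel:
    """Fit the SPI reference distribution on a daily precipitation series.

    ``pr`` must be indexed by date and cover at least five years; the
    gamma distribution (location fixed at zero) is fitted by maximum
    likelihood to the nonzero trailing-``window`` sums of each calendar
    month, with the zero-sum fraction handled as a point mass.
    """
    pr = pr.astype(float)
    if pr.isna().any():
        raise IntegrityError("precipitation series contains missing values")
    if (pr < 0).any():
        raise RangeError("negative precipitation")
    n_years = (pr.index.max() - pr.index.min()).days / 365.25
    if n_years < 5:
        raise DegenerateDataError(
            f"SPI fitting needs >= 5 years of data, got {n_years:.1f}"
        )
    sums = pr.rolling(window, min_periods=window).sum().dropna()
    month_params: dict[int, tuple[float, float, float]] = {}
    for month in range(1, 13):
        x = sums[sums.index.month == month].to_numpy(dtype=float)
        if len(x) == 0:
            continue
        q = float(np.mean(x <= 0.0))
        nz = x[x > 0.0]
        if len(nz) == 0:
            raise DegenerateDataError(
                f"all {window}-day sums are zero in calendar month {month}"
            )
        if np.ptp(nz) < 1e-9:
            raise DegenerateDataError(
                f"degenerate (constant) precipitation sums in month {month}"
            )
        shape, _, scale = stats.gamma.fit(nz, floc=0.0)
        month_params[month] = (q, float(shape), float(scale))
    return SPIModel(window=window, month_params=month_params)


def compute_spi(pr: pd.Series, window: int = 30, model: SPIModel | None = None) -> pd.Series:
    """Daily 30-day SPI for a date-indexed precipitation series.

    The first ``window - 1`` days have no trailing sum and are NaN.  An
    already-fitted :class:`SPIModel` may be supplied to transform new data
    (e.g. scenario simulations) on the observational reference.
    """
    pr = pr.astype(float)
    if model is None:
        model = fit_spi(pr, window=window)
    sums = pr.rolling(window, min_periods=window).sum()
    out = pd.Series(np.nan, index=pr.index)
    valid = sums.dropna()
    out.loc[valid.index] = model.transform(valid)
    return out


def add_derived_covariates(
    weather: pd.DataFrame,
    spi_window: int = 30,
    spi_models: Mapping[str, SPIModel] | None = None,
) -> tuple[pd.DataFrame, dict[str, SPIModel]]:
    """Append VPD and SPI columns per station; returns (table, SPI fits).

    The SPI fits are returned so scenario data can be transformed on the
    observational reference distribution.
    """
    df = weather.reset_index(drop=True).copy()
    df["VPD"] = compute_vpd(df["tas"].to_numpy(), df["RH"].to_numpy())
    spi_out = np.full(len(df), np.nan)
    fitted: dict[str, SPIModel] = {}
    for station, g in df.groupby("station_id", sort=False):
        pr = pd.Series(g["pr"].to_numpy(), index=pd.DatetimeIndex(g["date"]))
        model = None if spi_models is None else spi_models.get(str(station))
        if model is None:
            model = fit_spi(pr, window=spi_window)
        fitted[str(station)] = model
        spi_out[g.index] = compute_spi(pr, window=spi_window, model=model).to_numpy()
    df["SPI"] = spi_out
    return df, fitted


# ---------------------------------------------------------------------------
# standardization and splitting
# ---------------------------------------------------------------------------

def minmax_standardize(obs_series, scn_series) -> tuple[np.ndarray, np.ndarray]:
    """Scale both series by the pooled min/max so pooled min->0, max->1."""
    obs = np.asarray(obs_series, dtype=float)
    scn = np.asarray(scn_series, dtype=float)
    lo = np.nanmin([np.nanmin(obs), np.nanmin(scn)])
    hi = np.nanmax([np.nanmax(obs), np.nanmax(scn)])
    if not hi > lo:
        raise DegenerateDataError("pooled min equals pooled max")
    width = hi - lo
    return (obs - lo) / width, (scn - lo) / width


def stratified_split(
    environments: Sequence[PhenologyEnvironment],
    validation_fraction: float = 0.20,
    seed: int | None = None,
) -> dict[tuple[str, int], str]:
    """Assign each environment to 'training' or 'validation'.

    Stratified by harvest year so both sets carry the same year density;
    within each year-stratum the validation count is round(fraction * n).
    Strata with fewer than two environments go wholly to training with a
    warning.  Deterministic for a fixed seed.
    """
    if not 0.0 < validation_fraction < 1.0:
        raise ParameterError(
            f"validation fraction must be in (0, 1), got {validation_fraction}"
        )
    if seed is None:
        raise ParameterError("a split seed is required")
    rng = np.random.default_rng(seed)
    by_year: dict[int, list[PhenologyEnvironment]] = {}
    for env in environments:
        by_year.setdefault(env.harvest_year, []).append(env)
    assignment: dict[tuple[str, int], str] = {}
    for year in sorted(by_year):
        stratum = sorted(by_year[year], key=lambda e: e.key)
        if len(stratum) < 2:
            warnings.warn(
                f"year {year} has {len(stratum)} environment(s); assigned to training",
                stacklevel=2,
            )
            for env in stratum:
                assignment[env.key] = "training"
            continue
        n_val = int(round(validation_fraction * len(stratum)))
        n_val = min(max(n_val, 0), len(stratum) - 1)
        perm = rng.permutation(len(stratum))
        val_idx = set(perm[:n_val].tolist())
        for i, env in enumerate(stratum):
            assignment[env.key] = "validation" if i in val_idx else "training"
    return assignment


def split_environments(
    environments: Sequence[PhenologyEnvironment],
    assignment: Mapping[tuple[str, int], str],
) -> tuple[list[PhenologyEnvironment], list[PhenologyEnvironment]]:
    train = [e for e in environments if assignment[e.key] == "training"]
    val = [e for e in environments if assignment[e.key] == "validation"]
    return train, val


# ---------------------------------------------------------------------------
# scenario-ensemble and model file I/O
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: ScenarioEnsemble, directory) -> None:
    """Write one CSV per simulation plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sim in ensemble.simulations:
        fname = f"{sim.simulation_id}.csv"
        write_weather(sim.weather, directory / fname)
        entries.append(
            {
                "file": fname,
                "simulation_id": sim.simulation_id,
                "rcm": sim.rcm_id,
                "gcm": sim.gcm_id,
                "rcp": sim.rcp_label,
            }
        )
    manifest = {
        "reference_window": list(ensemble.reference_window),
        "projection_window": list(ensemble.projection_window),
        "simulations": entries,
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_ensemble(manifest_path) -> ScenarioEnsemble:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    sims = []
    for entry in manifest["simulations"]:
        weather = read_weather(base / entry["file"])
        sims.append(
            Simulation(
                simulation_id=str(entry["simulation_id"]),
                rcm_id=str(entry["rcm"]),
                gcm_id=str(entry["gcm"]),
                rcp_label=str(entry["rcp"]),
                weather=weather,
            )
        )
    return ScenarioEnsemble(
        simulations=sims,
        reference_window=tuple(manifest["reference_window"]),
        projection_window=tuple(manifest["projection_window"]),
    )


def save_model_json(obj: Mapping, path) -> None:
    payload = {"format_version": MODEL_FORMAT_VERSION, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"unsupported model file format_version {version!r}"
        )
    return payload
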