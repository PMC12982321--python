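"""Per-covariate DRC calibration.

For one covariate and one phenology phase a curve family is fitted by
minimizing the duration RMSE of a single-covariate thermal-time style
model: candidate parameters imply a daily dose series per environment;
the dose accumulated up to each environment's observed phase end defines
a common *required dose* (the median across training environments); the
predicted duration is the (linearly interpolated) day on which the
cumulative dose reaches that requirement.

Fitting is a two-step constrained local search:

1. a coarse pass from quantile-based starting values within quantile
   bounds (at most ``coarse_max_iter`` evaluations, relative tolerance
   1e-2);
2. a fine pass restarted at the coarse optimum with per-parameter bounds
   ``[v - |v|, v + |v|]`` (zero-valued optima widened by 0.1) and
   relative tolerance 1e-8.

Robustness comes from an ensemble of 20 such fits, each on a random 80 %
subsample of the training environments (64 % of all data after the 80/20
train/validation split); the elementwise median of the ensemble is the
final estimate.  Per covariate the best family is the one with the
highest Pearson correlation between observed and modelled durations.

For the temperature covariates and global radiation only the
cardinal-temperature (Wang-Engel) family is calibrated; for relative
humidity, SPI and VPD all four families compete — 16 covariate-family
candidates per phase in the full seven-covariate setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .drc import DRCSpec, PARAM_NAMES, PHASE_BOUNDS, eval_drc_array
from .errors import (
    CalibrationError,
    DegenerateDataError,
    SelectionError,
)
from .io_covariates import PhenologyEnvironment
from .weather_index import WeatherIndex

#: families calibrated per covariate: the bounded cardinal-temperature
#: response for temperatures and radiation, all four otherwise
TEMPERATURE_LIKE = frozenset({"tasmin", "tas", "tasmax", "GR"})
ALL_FAMILIES = ("linear", "broken_stick", "asymptotic", "wang_engel")

LOSS_SENTINEL = 1e6  # optimizer-safe stand-in for an infinite loss
_ORDER_MARGIN = 1e-3  # strictness margin for psi_base < psi_opt < psi_max


def candidate_families(covariate: str) -> tuple[str, ...]:
    if covariate in TEMPERATURE_LIKE:
        return ("wang_engel",)
    return ALL_FAMILIES


@dataclass(frozen=True)
class CalibrationConfig:
    coarse_max_iter: int = 500
    fine_max_iter_factor: int = 1000  # multiplied by the parameter-vector length
    abs_tol: float = 1e-24
    rel_tol_coarse: float = 1e-2
    rel_tol_fine: float = 1e-8
    ensemble_runs: int = 20
    subsample_fraction: float = 0.8
    quantile_starts: tuple[float, float, float] = (0.05, 0.5, 0.95)
    zero_bound_eps: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (self.abs_tol > 0 and self.rel_tol_coarse > 0 and self.rel_tol_fine > 0):
            raise ValueError("tolerances must be positive")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.ensemble_runs < 1:
            raise ValueError("ensemble_runs must be >= 1")


@dataclass(frozen=True)
class PhaseData:
    """Prepared per-environment covariate windows for one covariate x phase.

    ``values`` is (n_env, horizon) with NaN past each station's coverage;
    ``durations`` the observed whole-day phase lengths.  Row ``i``'s dose
    after ``d`` days is ``cumsum(f(values[i, :d]))``.
    """

    covariate: str
    phase: str
    env_keys: tuple
    values: np.ndarray
    durations: np.ndarray

    @property
    def n_env(self) -> int:
        return len(self.durations)

    def subset(self, idx: np.ndarray) -> "PhaseData":
        return PhaseData(
            self.covariate,
            self.phase,
            tuple(self.env_keys[i] for i in idx),
            self.values[idx],
            self.durations[idx],
        )


def prepare_phase_data(
    environments: Sequence[PhenologyEnvironment],
    weather: WeatherIndex,
    covariate: str,
    phase: str,
    horizon_factor: float = 2.0,
) -> PhaseData:
    """Extract per-environment covariate windows for loss evaluation.

    The window extends to ``horizon_factor`` times the longest observed
    duration so mis-parameterized candidates can still cross (or be
    censored at the horizon).
    """
    start_name, end_name = PHASE_BOUNDS[phase]
    keys, starts, durs = [], [], []
    for env in environments:
        start = getattr(env, start_name)
        end = getattr(env, end_name)
        if start is None or end is None:
            continue
        keys.append(env.key)
        starts.append((env.station_id, start))
        durs.append((end - start).days)
    if not keys:
        raise CalibrationError(f"no environment observes phase {phase!r}")
    durations = np.asarray(durs, dtype=float)
    horizon = int(np.ceil(horizon_factor * durations.max()))
    values = np.empty((len(keys), horizon))
    for i, (station, start) in enumerate(starts):
        values[i] = weather.window(station, covariate, start, horizon)
    return PhaseData(covariate, phase, tuple(keys), values, durations)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _predicted_durations(cum: np.ndarray, required: float) -> np.ndarray:
    """Linearly interpolated crossing day of ``required`` per row.

    Rows that never reach the requirement are censored at the horizon.
    """
    n, horizon = cum.shape
    reached = cum >= required
    any_reached = reached.any(axis=1)
    k = np.argmax(reached, axis=1)
    prev = np.where(k > 0, cum[np.arange(n), np.maximum(k - 1, 0)], 0.0)
    denom = cum[np.arange(n), k] - prev
    frac = np.where(denom > 0, (required - prev) / np.maximum(denom, 1e-300), 1.0)
    pred = k + np.clip(frac, 0.0, 1.0)
    return np.where(any_reached, pred, float(horizon))


def calibration_loss(
    params: Mapping[str, float],
    family: str,
    data: PhaseData,
) -> float:
    """Duration RMSE (days) of a candidate single-covariate dose model.

    The required dose is the median across environments of the dose
    accumulated up to each observed phase end; all-zero (or negative)
    accumulation yields an optimizer-safe large sentinel instead of an
    infinity.
    """
    if family == "wang_engel":
        b, o, m = params["psi_base"], params["psi_opt"], params["psi_max"]
        if not (b < o < m):
            gap = max(b - o, 0.0) + max(o - m, 0.0)
            return LOSS_SENTINEL * (1.0 + gap)
    resp = eval_drc_array(family, params, data.values)
    resp = np.where(np.isnan(resp), 0.0, resp)
    cum = np.cumsum(resp, axis=1)
    idx = np.arange(data.n_env)
    at_end = cum[idx, data.durations.astype(int) - 1]
    required = float(np.median(at_end))
    if not np.isfinite(required) or required <= 0.0:
        return LOSS_SENTINEL
    pred = _predicted_durations(cum, required)
    return float(np.sqrt(np.mean((pred - data.durations) ** 2)))


def required_dose(params: Mapping[str, float], family: str, data: PhaseData) -> float:
    """Median accumulated dose at the observed phase ends."""
    resp = eval_drc_array(family, params, data.values)
    resp = np.where(np.isnan(resp), 0.0, resp)
    cum = np.cumsum(resp, axis=1)
    at_end = cum[np.arange(data.n_env), data.durations.astype(int) - 1]
    return float(np.median(at_end))


def predict_durations(
    params: Mapping[str, float], family: str, data: PhaseData, required: float | None = None
) -> np.ndarray:
    resp = eval_drc_array(family, params, data.values)
    resp = np.where(np.isnan(resp), 0.0, resp)
    cum = np.cumsum(resp, axis=1)
    if required is None:
        at_end = cum[np.arange(data.n_env), data.durations.astype(int) - 1]
        required = float(np.median(at_end))
    return _predicted_durations(cum, required)


# ---------------------------------------------------------------------------
# starting values and bounds
# ---------------------------------------------------------------------------

def initial_params(
    family: str,
    covariate_values: np.ndarray,
    phase: str | None = None,
    config: CalibrationConfig | None = None,
) -> tuple[dict, dict, dict]:
    """Quantile-based starts and coarse bounds for a DRC family.

    Parameters in covariate units (psi_base, psi_opt, psi_max) start at
    the configured quantiles (defaults 0.05 / 0.5 / 0.95) of the observed
    covariate sample; unit-free parameters start at documented defaults
    (slope 1, intercept 0, Asym 1, lrc 0, r 1).  Returns
    ``(start, lower, upper)`` dicts keyed by parameter name.
    """
    config = config or CalibrationConfig()
    x = np.asarray(covariate_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2 or np.ptp(x) < 1e-12:
        raise DegenerateDataError(
            "covariate sample is constant or too small for quantile starts"
        )
    q_lo, q_mid, q_hi = config.quantile_starts
    lo_q, mid_q, hi_q = np.quantile(x, [q_lo, q_mid, q_hi])
    xmin, xmax = float(x.min()), float(x.max())
    span = xmax - xmin

    if family == "linear":
        start = {"intercept": 0.0, "slope": 1.0}
        lower = {"intercept": -10.0, "slope": -10.0}
        upper = {"intercept": 10.0, "slope": 10.0}
    elif family == "broken_stick":
        start = {"psi_base": float(lo_q), "slope": 1.0}
        lower = {"psi_base": xmin - 0.1 * span, "slope": 0.0}
        upper = {"psi_base": float(mid_q), "slope": 10.0}
    elif family == "asymptotic":
        start = {"psi_base": float(lo_q), "lrc": 0.0, "asym": 1.0}
        lower = {"psi_base": xmin - 0.1 * span, "lrc": -5.0, "asym": 1e-3}
        upper = {"psi_base": float(mid_q), "lrc": 5.0, "asym": 10.0}
    elif family == "wang_engel":
        start = {
            "psi_base": float(lo_q),
            "psi_opt": float(mid_q),
            "psi_max": float(hi_q),
            "r": 1.0,
        }
        lower = {
            "psi_base": xmin - 0.1 * span,
            "psi_opt": float(np.quantile(x, 0.10)),
            "psi_max": float(np.quantile(x, 0.75)),
            "r": 1e-3,
        }
        upper = {
            "psi_base": float(np.quantile(x, 0.25)),
            "psi_opt": float(np.quantile(x, 0.90)),
            "psi_max": xmax + 0.2 * span,
            "r": 10.0,
        }
    else:
        raise ValueError(f"unknown family {family!r}")
    return start, lower, upper


# ---------------------------------------------------------------------------
# two-step fit
# ---------------------------------------------------------------------------

def _cobyla(fun, x0, lower, upper, ordering_idx, maxiter, tol):
    """COBYLA in a per-parameter scaled space.

    Each parameter is divided by a quarter of its bound width so a unit
    trust-region step explores a comparable fraction of every bound,
    regardless of the covariate's units (degrees vs. J/cm^2).
    """
    x0 = np.asarray(x0, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    scale = np.maximum((upper - lower) / 4.0, 1e-6)

    def sfun(z):
        return fun(z * scale)

    cons = []
    lo_s, hi_s = lower / scale, upper / scale
    for i in range(len(x0)):
        cons.append({"type": "ineq", "fun": lambda z, i=i: z[i] - lo_s[i]})
        cons.append({"type": "ineq", "fun": lambda z, i=i: hi_s[i] - z[i]})
    if ordering_idx is not None:
        b, o, m = ordering_idx
        cons.append(
            {"type": "ineq",
             "fun": lambda z: z[o] * scale[o] - z[b] * scale[b] - _ORDER_MARGIN}
        )
        cons.append(
            {"type": "ineq",
             "fun": lambda z: z[m] * scale[m] - z[o] * scale[o] - _ORDER_MARGIN}
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            sfun,
            x0 / scale,
            method="COBYLA",
            constraints=cons,
            tol=tol,
            options={"maxiter": int(maxiter), "rhobeg": 1.0},
        )
    res.x = np.asarray(res.x, dtype=float) * scale
    return res


def fit_drc_two_step(
    data: PhaseData,
    family: str,
    config: CalibrationConfig | None = None,
) -> dict:
    """Coarse-then-fine constrained fit of one DRC family.

    Step 1 searches from quantile starts within quantile bounds; step 2
    restarts at the step-1 optimum with bounds ``[v - |v|, v + |v|]``
    per parameter (zero optima widened to ``+- zero_bound_eps``) and the
    fine relative tolerance.  Raises :class:`CalibrationError` carrying
    the best parameters seen if neither step produced a usable loss.
    """
    config = config or CalibrationConfig()
    names = PARAM_NAMES[family]
    start, lower, upper = initial_params(family, data.values, data.phase, config)
    x0 = np.array([start[n] for n in names])
    lo1 = np.array([lower[n] for n in names])
    hi1 = np.array([upper[n] for n in names])
    ordering = (
        tuple(names.index(k) for k in ("psi_base", "psi_opt", "psi_max"))
        if family == "wang_engel"
        else None
    )

    def fun(x):
        return calibration_loss(dict(zip(names, x)), family, data)

    res1 = _cobyla(fun, x0, lo1, hi1, ordering, config.coarse_max_iter, config.rel_tol_coarse)
    x1 = np.asarray(res1.x, dtype=float)
    loss1 = fun(x1)

    width = np.maximum(np.abs(x1), config.zero_bound_eps)
    lo2, hi2 = x1 - width, x1 + width
    res2 = _cobyla(
        fun, x1, lo2, hi2, ordering, config.fine_max_iter_factor * len(names), config.rel_tol_fine
    )
    x2 = np.asarray(res2.x, dtype=float)
    loss2 = fun(x2)

    best_x, best_loss = (x2, loss2) if loss2 <= loss1 else (x1, loss1)
    params = dict(zip(names, (float(v) for v in best_x)))
    if best_loss >= LOSS_SENTINEL:
        raise CalibrationError(
            f"{family} fit for {data.covariate}/{data.phase} did not converge",
            best_params=params,
        )
    if family == "wang_engel" and not (
        params["psi_base"] < params["psi_opt"] < params["psi_max"]
    ):
        raise CalibrationError(
            f"{family} fit violated the cardinal ordering", best_params=params
        )
    return params


# ---------------------------------------------------------------------------
# ensemble calibration and family selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    covariate: str
    phase: str
    family: str
    ensemble_params: tuple
    median_params: Mapping[str, float]
    required_dose: float
    score_cor: float
    score_rmse: float
    n_failed_runs: int = 0

    @property
    def spec(self) -> DRCSpec:
        return DRCSpec(self.family, self.covariate, self.phase, dict(self.median_params))

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self.family])

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "phase": self.phase,
            "family": self.family,
            "ensemble_params": [dict(p) for p in self.ensemble_params],
            "median_params": dict(self.median_params),
            "required_dose": self.required_dose,
            "score_cor": self.score_cor,
            "score_rmse": self.score_rmse,
            "n_failed_runs": self.n_failed_runs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationResult":
        return cls(
            covariate=d["covariate"],
            phase=d["phase"],
            family=d["family"],
            ensemble_params=tuple(dict(p) for p in d["ensemble_params"]),
            median_params=dict(d["median_params"]),
            required_dose=float(d["required_dose"]),
            score_cor=float(d["score_cor"]),
            score_rmse=float(d["score_rmse"]),
            n_failed_runs=int(d.get("n_failed_runs", 0)),
        )


def ensemble_calibrate(
    data: PhaseData,
    family: str,
    config: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Median-of-ensemble calibration on seeded 80 % subsamples."""
    config = config or CalibrationConfig()
    names = PARAM_NAMES[family]
    rng = np.random.default_rng(config.seed)
    n_sub = max(int(round(config.subsample_fraction * data.n_env)), len(names) + 1)
    n_sub = min(n_sub, data.n_env)
    members: list[dict] = []
    n_failed = 0
    for _ in range(config.ensemble_runs):
        idx = rng.choice(data.n_env, size=n_sub, replace=False)
        idx.sort()
        try:
            members.append(fit_drc_two_step(data.subset(idx), family, config))
        except CalibrationError:
            n_failed += 1
    if n_failed > config.ensemble_runs // 2 or not members:
        raise CalibrationError(
            f"{n_failed}/{config.ensemble_runs} ensemble runs failed for "
            f"{family} on {data.covariate}/{data.phase}"
        )
    if n_failed:
        warnings.warn(
            f"{n_failed} of {config.ensemble_runs} ensemble runs failed "
            f"({family}, {data.covariate}/{data.phase}); excluded from the median",
            stacklevel=2,
        )
    median_params = {
        n: float(np.median([m[n] for m in members])) for n in names
    }
    if family == "wang_engel" and not (
        median_params["psi_base"] < median_params["psi_opt"] < median_params["psi_max"]
    ):
        raise CalibrationError(
            "ensemble median violates the cardinal ordering", best_params=median_params
        )
    req = required_dose(median_params, family, data)
    pred = predict_durations(median_params, family, data, required=req)
    obs = data.durations
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(pred) < 1e-12 or np.ptp(obs) < 1e-12:
        cor = float("nan")
    else:
        cor = float(stats.pearsonr(obs, pred).statistic)
    return CalibrationResult(
        covariate=data.covariate,
        phase=data.phase,
        family=family,
        ensemble_params=tuple(members),
        median_params=median_params,
        required_dose=req,
        score_cor=cor,
        score_rmse=rmse,
        n_failed_runs=n_failed,
    )


def select_best_drc(results: Sequence[CalibrationResult]) -> CalibrationResult:
    """Highest Pearson correlation wins; ties fall to fewer parameters,
    then to lower RMSE."""
    if not results:
        raise SelectionError("no calibration results to select from")

    def sort_key(r: CalibrationResult):
        cor = r.score_cor if np.isfinite(r.score_cor) else -np.inf
        return (-cor, r.n_params, r.score_rmse)

    return sorted(results, key=sort_key)[0]


def calibrate_covariate(
    environments: Sequence[PhenologyEnvironment],
    weather: WeatherIndex,
    covariate: str,
    phase: str,
    config: CalibrationConfig | None = None,
) -> tuple[CalibrationResult, list[CalibrationResult]]:
    """Calibrate every candidate family for one covariate x phase and pick
    the best; returns (winner, all results)."""
    config = config or CalibrationConfig()
    data = prepare_phase_data(environments, weather, covariate, phase)
    results = []
    for i, family in enumerate(candidate_families(covariate)):
        fam_cfg = replace(config, seed=config.seed + 1000 * i)
        try:
            results.append(ensemble_calibrate(data, family, fam_cfg))
        except (CalibrationError, DegenerateDataError) as exc:
            warnings.warn(
                f"family {family} failed for {covariate}/{phase}: {exc}", stacklevel=2
            )
    return select_best_drc(results), results


def calibrate_phase(
    environments: Sequence[PhenologyEnvironment],
    weather: WeatherIndex,
    phase: str,
    covariates: Sequence[str],
    config: CalibrationConfig | None = None,
) -> dict[str, CalibrationResult]:
    """Best calibrated DRC per covariate for one phase."""
    out: dict[str, CalibrationResult] = {}
    for covariate in covariates:
        winner, _ = calibrate_covariate(environments, weather, covariate, phase, config)
        out[covariate] = winner
    return out
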