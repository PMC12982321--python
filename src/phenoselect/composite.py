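"""Composite phenology models: additive binomial-logit over accumulated doses.

For a phase ``p`` and a covariate subset ``C`` the model is

    Pr(phase reached by day d) = logit^-1( b0 + sum_{c in C} b_c * Z_c(d) )

where ``Z_c(d)`` is the running dose of covariate ``c`` accumulated with
its pre-calibrated dose-response curve from the phase start.  The model
is purely additive — collinearity between doses is absorbed by the GLM,
interactions are deliberately out of scope.

Training rows are daily: per environment, one row for each day offset
``d = 0 .. 2*duration - 1``, labelled 0 before the observed phase end and
1 from it onward; the equal-length post-end buffer balances the classes.
The decision threshold on the fitted probability is the Youden-optimal
point of a ROC analysis.  All ``2^k - 1`` covariate subsets are
enumerated — 127 per phase for seven covariates, 508 over four phases.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .drc import DRCSpec, PHASE_BOUNDS, eval_drc_array
from .errors import (
    ConfigurationError,
    EvaluationError,
    FitError,
    IntegrityError,
    ValidationError,
)
from .io_covariates import PhenologyEnvironment
from .weather_index import WeatherIndex

logger = logging.getLogger(__name__)

_RIDGE_LAMBDA = 1e-6  # fallback penalty on slopes under complete separation


def enumerate_combinations(covariates: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty covariate subsets, ordered by (size, lexicographic)."""
    if len(set(covariates)) != len(covariates):
        raise ValidationError("duplicate covariate names")
    if not 1 <= len(covariates) <= 7:
        raise ValidationError("between 1 and 7 covariates expected")
    ordered = sorted(covariates)
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(ordered) + 1):
        subsets.extend(itertools.combinations(ordered, size))
    return subsets


def subset_id(subset: Sequence[str]) -> str:
    return "+".join(sorted(subset))


@dataclass(frozen=True)
class CompositeModel:
    """Fitted binomial-logit composite model for one phase."""

    phase: str
    covariates: tuple[str, ...]
    drc_map: Mapping[str, DRCSpec]
    intercept: float
    coefficients: Mapping[str, float]
    decision_threshold: float | None = None

    def __post_init__(self):
        if not 1 <= len(self.covariates) <= 7:
            raise ValidationError("composite model needs 1..7 covariates")
        if set(self.coefficients) != set(self.covariates):
            raise ValidationError("coefficients must match the covariate set")
        tau = self.decision_threshold
        if tau is not None and not 0.0 < tau < 1.0:
            raise ValidationError("decision threshold must lie strictly in (0, 1)")

    @property
    def complexity(self) -> int:
        return len(self.covariates)

    @property
    def model_id(self) -> str:
        return f"{self.phase}:{subset_id(self.covariates)}"

    def inclusion_flags(self, all_covariates: Sequence[str]) -> dict[str, int]:
        return {c: int(c in self.covariates) for c in all_covariates}

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "covariates": list(self.covariates),
            "drc_map": {c: s.to_dict() for c, s in self.drc_map.items()},
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "decision_threshold": self.decision_threshold,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompositeModel":
        return cls(
            phase=d["phase"],
            covariates=tuple(d["covariates"]),
            drc_map={c: DRCSpec.from_dict(s) for c, s in d["drc_map"].items()},
            intercept=float(d["intercept"]),
            coefficients={c: float(v) for c, v in d["coefficients"].items()},
            decision_threshold=(
                None if d.get("decision_threshold") is None
                else float(d["decision_threshold"])
            ),
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    environments: Sequence[PhenologyEnvironment],
    weather: WeatherIndex,
    drc_map: Mapping[str, DRCSpec],
    phase: str,
) -> pd.DataFrame:
    """Daily training rows with running doses and the reached/not label.

    One row per environment and day offset ``d = 0 .. 2*duration - 1``;
    ``Z_<cov>`` is the dose accumulated over days ``0..d`` and the label
    is 1 iff ``d >= duration``.  Raises if weather does not cover the
    buffered window.
    """
    start_name, end_name = PHASE_BOUNDS[phase]
    frames = []
    for env in environments:
        start = getattr(env, start_name)
        end = getattr(env, end_name)
        if start is None or end is None:
            raise IntegrityError(f"environment {env.key} does not observe {phase}")
        dur = (end - start).days
        n_days = 2 * dur
        rows = {
            "station_id": env.station_id,
            "harvest_year": env.harvest_year,
            "day": np.arange(n_days),
        }
        for cov, spec in drc_map.items():
            x = weather.window(env.station_id, cov, start, n_days)
            if np.isnan(x).any() and cov not in ("SPI",):
                raise IntegrityError(
                    f"weather does not cover the buffered {phase} window for {env.key}"
                )
            resp = eval_drc_array(spec.family, spec.params, x)
            rows[f"Z_{cov}"] = np.cumsum(np.where(np.isnan(resp), 0.0, resp))
        rows["label"] = (np.arange(n_days) >= dur).astype(int)
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# logistic fit and ROC threshold
# ---------------------------------------------------------------------------

def fit_composite(
    design: pd.DataFrame,
    subset: Sequence[str],
    drc_map: Mapping[str, DRCSpec],
    phase: str,
) -> CompositeModel:
    """Maximum-likelihood logistic fit of one covariate subset.

    Complete separation (non-finite or exploding ML estimates) falls back
    to a lightly ridge-penalized fit (lambda = 1e-6 on the slopes).
    """
    subset = tuple(sorted(subset))
    cols = [f"Z_{c}" for c in subset]
    missing = [c for c in cols if c not in design.columns]
    if missing:
        raise FitError(f"design lacks dose column(s) {missing}")
    y = design["label"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise FitError("design contains a single class")
    X = design[cols].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    params = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)
        params = np.asarray(fit.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e8:
            params = None
    except Exception:  # separation / singular design
        params = None
    if params is None:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(
            penalty="l2", C=1.0 / _RIDGE_LAMBDA, solver="lbfgs", max_iter=1000
        )
        lr.fit(X, y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    return CompositeModel(
        phase=phase,
        covariates=subset,
        drc_map={c: drc_map[c] for c in subset},
        intercept=float(params[0]),
        coefficients={c: float(b) for c, b in zip(subset, params[1:])},
    )


def roc_threshold(probabilities, labels) -> float:
    """Youden-optimal probability threshold.

    Candidates are the midpoints of consecutive sorted unique predicted
    probabilities; the smallest candidate maximizing
    J = sensitivity + specificity - 1 is returned.  A warning is issued
    when the labels carry no signal (max J ~ 0).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise FitError("ROC threshold needs both classes")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    order = np.argsort(p, kind="mergesort")
    p_sorted, y_sorted = p[order], y[order]
    # tp(i) / fp(i): positives / negatives among indices >= i (pred = 1)
    tp_right = np.concatenate([np.cumsum(y_sorted[::-1])[::-1], [0]])
    fp_right = np.concatenate([np.cumsum(1 - y_sorted[::-1])[::-1], [0]])
    boundaries = np.flatnonzero(np.diff(p_sorted) > 0) + 1
    if len(boundaries) == 0:
        candidates = np.array([min(max(p_sorted[0], 1e-9), 1 - 1e-9)])
        split_idx = np.array([0])
    else:
        candidates = (p_sorted[boundaries - 1] + p_sorted[boundaries]) / 2.0
        split_idx = boundaries
    j = tp_right[split_idx] / n_pos + (n_neg - fp_right[split_idx]) / n_neg - 1.0
    best = float(np.max(j))
    if best < 1e-9:
        warnings.warn("ROC analysis found no usable signal (J ~ 0)", stacklevel=2)
    tau = float(candidates[np.flatnonzero(j >= best - 1e-12)[0]])
    return min(max(tau, 1e-9), 1.0 - 1e-9)


def with_threshold(model: CompositeModel, design: pd.DataFrame) -> CompositeModel:
    """Attach the ROC decision threshold derived on the training design."""
    cols = [f"Z_{c}" for c in model.covariates]
    eta = model.intercept + design[cols].to_numpy(dtype=float) @ np.array(
        [model.coefficients[c] for c in model.covariates]
    )
    tau = roc_threshold(expit(eta), design["label"].to_numpy())
    return CompositeModel(
        phase=model.phase,
        covariates=model.covariates,
        drc_map=model.drc_map,
        intercept=model.intercept,
        coefficients=model.coefficients,
        decision_threshold=tau,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

CENSORED = None  # a censored prediction is an explicit None end date


def predict_phase_end(
    model: CompositeModel,
    weather: WeatherIndex,
    station_id,
    start: date,
    horizon: int,
) -> tuple[date | None, float]:
    """First day the exceedance probability reaches the decision threshold.

    Returns ``(end_date, duration_days)``; a phase that never crosses the
    threshold within ``horizon`` days is censored: ``(None, nan)``.
    """
    if model.decision_threshold is None:
        raise ConfigurationError("model has no decision threshold")
    eta = np.full(horizon, model.intercept)
    for cov in model.covariates:
        spec = model.drc_map[cov]
        x = weather.window(station_id, cov, start, horizon)
        resp = eval_drc_array(spec.family, spec.params, x)
        eta = eta + model.coefficients[cov] * np.cumsum(
            np.where(np.isnan(resp), 0.0, resp)
        )
    prob = expit(eta)
    reached = prob >= model.decision_threshold
    if not reached.any():
        return CENSORED, float("nan")
    d = int(np.argmax(reached))
    return start + timedelta(days=d), float(d)


def chain_phases(
    models: Mapping[str, CompositeModel],
    weather: WeatherIndex,
    station_id,
    sowing: date,
    horizons: Mapping[str, int] | None = None,
    default_horizon: int = 400,
) -> dict[str, date | None]:
    """Consecutive whole-season prediction from a sowing date.

    Each phase starts at the previous phase's predicted end; once a phase
    is censored every later stage is censored too.  Returns predicted
    dates keyed by stage name (emergence, jointing, heading, senescence).
    """
    phases = list(PHASE_BOUNDS)
    missing = [p for p in phases if p not in models]
    if missing:
        raise ConfigurationError(f"missing composite model(s) for phase(s) {missing}")
    out: dict[str, date | None] = {}
    start: date | None = sowing
    for phase in phases:
        stage = PHASE_BOUNDS[phase][1]
        if start is None:
            out[stage] = CENSORED
            continue
        horizon = (horizons or {}).get(phase, default_horizon)
        end, _ = predict_phase_end(models[phase], weather, station_id, start, horizon)
        out[stage] = end
        start = end
    return out


def default_horizon(durations: Sequence[float], factor: float = 2.0) -> int:
    """Prediction horizon: ``factor`` times the 95th percentile duration."""
    return int(np.ceil(factor * np.percentile(np.asarray(durations, dtype=float), 95)))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_model(predicted, observed) -> dict[str, float]:
    """RMSE, MAE (days) and Pearson r over non-censored pairs.

    Censored or missing predictions are excluded with a logged count;
    fewer than three valid pairs is an error, constant vectors leave the
    correlation undefined (NaN).
    """
    pred = np.asarray(
        [np.nan if p is None else p for p in predicted], dtype=float
    )
    obs = np.asarray(observed, dtype=float)
    valid = ~np.isnan(pred) & ~np.isnan(obs)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("evaluate_model: excluded %d censored/missing pair(s)", n_dropped)
    pred, obs = pred[valid], obs[valid]
    if len(pred) < 3:
        raise EvaluationError(
            f"need >= 3 valid prediction/observation pairs, got {len(pred)}"
        )
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(pred) < 1e-12 or np.ptp(obs) < 1e-12:
        r = float("nan")
    else:
        r = float(stats.pearsonr(obs, pred).statistic)
    return {"rmse": rmse, "mae": mae, "pearson_r": r, "n": len(pred), "n_censored": n_dropped}


# ---------------------------------------------------------------------------
# grid fitting
# ---------------------------------------------------------------------------

def fit_model_grid(
    environments: Sequence[PhenologyEnvironment],
    weather: WeatherIndex,
    drc_map: Mapping[str, DRCSpec],
    phase: str,
) -> list[CompositeModel]:
    """Fit every non-empty covariate subset for one phase, with thresholds."""
    design = build_design(environments, weather, drc_map, phase)
    models = []
    for subset in enumerate_combinations(list(drc_map)):
        model = fit_composite(design, subset, drc_map, phase)
        models.append(with_threshold(model, design))
    return models
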