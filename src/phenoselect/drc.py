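"""Dose-response curve (DRC) families and daily dose accumulation.

A DRC maps a daily environmental covariate value (temperature, radiation,
humidity, ...) to a unitless daily development increment.  Summing the
increments over a phase window yields the accumulated dose

    Z = sum_d f(x_d; theta),

the covariate-specific predictor of phase completion.  Four families are
supported:

``linear``
    ``intercept + x * slope`` — unbounded, may go negative.
``broken_stick``
    zero below a base threshold ``psi_base``, then linear with ``slope``
    (the classical growing-degree-day form when ``psi_base=0, slope=1``).
``asymptotic``
    ``Asym * (1 - exp(-exp(lrc) * (x - psi_base)))`` clipped at zero —
    saturating response with asymptote ``Asym`` and log rate constant
    ``lrc``.
``wang_engel``
    the cardinal-temperature response with base/optimum/maximum
    (``psi_base < psi_opt < psi_max``): zero outside the open interval,
    maximum ``r`` exactly at the optimum, with shape exponent

        alpha = ln 2 / ln((psi_max - psi_base) / (psi_opt - psi_base)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError

FAMILIES = ("linear", "broken_stick", "asymptotic", "wang_engel")

PARAM_NAMES: Mapping[str, tuple[str, ...]] = {
    "linear": ("intercept", "slope"),
    "broken_stick": ("psi_base", "slope"),
    "asymptotic": ("psi_base", "lrc", "asym"),
    "wang_engel": ("psi_base", "psi_opt", "psi_max", "r"),
}

PHASES = (
    "sowing-emergence",
    "emergence-jointing",
    "jointing-heading",
    "heading-senescence",
)

#: phase name -> (start stage, end stage)
PHASE_BOUNDS: Mapping[str, tuple[str, str]] = {
    "sowing-emergence": ("sowing", "emergence"),
    "emergence-jointing": ("emergence", "jointing"),
    "jointing-heading": ("jointing", "heading"),
    "heading-senescence": ("heading", "senescence"),
}


def wang_engel_alpha(psi_base: float, psi_opt: float, psi_max: float) -> float:
    """Shape exponent of the cardinal-temperature response.

    alpha = ln(2) / ln((psi_max - psi_base) / (psi_opt - psi_base));
    equal to 1 when the optimum sits at the midpoint of the range and to
    0.5 when the range is four times the base-to-optimum distance.
    """
    if not (psi_base < psi_opt < psi_max):
        raise ValidationError(
            f"wang_engel requires psi_base < psi_opt < psi_max, got "
            f"({psi_base}, {psi_opt}, {psi_max})"
        )
    return math.log(2.0) / math.log((psi_max - psi_base) / (psi_opt - psi_base))


@dataclass(frozen=True)
class DRCSpec:
    """One dose-response curve: family, covariate, phase and parameters."""

    family: str
    covariate: str
    phase: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown DRC family {self.family!r}")
        names = PARAM_NAMES[self.family]
        missing = [n for n in names if n not in self.params]
        if missing:
            raise ValidationError(
                f"{self.family} DRC missing parameters {missing}"
            )
        vals = [float(self.params[n]) for n in names]
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"{self.family} DRC has non-finite parameters")
        if self.family == "wang_engel":
            b, o, m, _ = (self.params[n] for n in names)
            if not (b < o < m):
                raise ValidationError(
                    "wang_engel requires psi_base < psi_opt < psi_max, got "
                    f"({b}, {o}, {m})"
                )
        if self.family == "asymptotic" and not self.params["asym"] > 0:
            raise ValidationError("asymptotic requires Asym > 0")

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self.family])

    def response(self, x) -> np.ndarray | float:
        """Evaluate the curve at covariate value(s) ``x`` (vectorized)."""
        scalar = np.isscalar(x)
        out = eval_drc_array(self.family, self.params, np.asarray(x, dtype=float))
        return float(out) if scalar else out

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "covariate": self.covariate,
            "phase": self.phase,
            "params": {k: float(v) for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DRCSpec":
        return cls(d["family"], d["covariate"], d["phase"], dict(d["params"]))


def eval_drc_array(family: str, params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    """Family dispatch on a float array; NaN inputs map to NaN responses."""
    x = np.asarray(x, dtype=float)
    if family == "linear":
        return params["intercept"] + x * params["slope"]
    if family == "broken_stick":
        b = params["psi_base"]
        return np.where(x > b, (x - b) * params["slope"], 0.0)
    if family == "asymptotic":
        b, lrc, asym = params["psi_base"], params["lrc"], params["asym"]
        # exponent clipped: far below psi_base the response is exactly 0 anyway
        z = np.clip(-np.exp(lrc) * (x - b), None, 50.0)
        r = asym * (1.0 - np.exp(z))
        return np.where(r > 0.0, r, 0.0)
    if family == "wang_engel":
        b, o, m, r = (params[k] for k in ("psi_base", "psi_opt", "psi_max", "r"))
        alpha = wang_engel_alpha(b, o, m)
        out = np.zeros_like(x)
        nan = np.isnan(x)
        inside = (x > b) & (x < m)
        xi = x[inside]
        ob = (o - b) ** alpha
        xb = (xi - b) ** alpha
        val = r * (2.0 * xb * ob - xb**2) / ob**2
        out[inside] = np.maximum(val, 0.0)  # guards round-off at the edges
        out[nan] = np.nan
        return out
    raise ValidationError(f"unknown DRC family {family!r}")


def eval_drc(spec: DRCSpec, x) -> np.ndarray | float:
    """Functional form of :meth:`DRCSpec.response`."""
    return spec.response(x)


@dataclass(frozen=True)
class DoseSeries:
    """Per-day responses and their running sum over a phase window."""

    dates: pd.DatetimeIndex
    responses: np.ndarray
    cumulative: np.ndarray

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0

    @property
    def n_days(self) -> int:
        return len(self.responses)


def accumulate_dose(
    spec: DRCSpec,
    weather: pd.DataFrame,
    start: date,
    end: date,
    station_id=None,
) -> DoseSeries:
    """Accumulate daily responses over the half-open window ``[start, end)``.

    ``weather`` is a daily weather table (see :mod:`phenoselect.io_covariates`)
    containing the spec's covariate column.  Half-open windows let chained
    phases share a boundary day without double-counting it.
    """
    df = weather
    if station_id is not None:
        df = df[df["station_id"] == station_id]
    if spec.covariate not in df.columns:
        raise IntegrityError(
            f"covariate {spec.covariate!r} not present in weather table"
        )
    start_ts = pd.Timestamp(start)
    end_ts = pd.Timestamp(end)
    n_days = (end_ts - start_ts).days
    if n_days <= 0:
        idx = pd.DatetimeIndex([])
        return DoseSeries(idx, np.empty(0), np.empty(0))
    window = df[(df["date"] >= start_ts) & (df["date"] < end_ts)]
    if len(window) != n_days:
        raise IntegrityError(
            f"weather covers {len(window)} of {n_days} days in "
            f"[{start}, {end}) for station {station_id!r}"
        )
    x = window[spec.covariate].to_numpy(dtype=float)
    resp = np.asarray(spec.response(x), dtype=float)
    return DoseSeries(
        pd.DatetimeIndex(window["date"]), resp, np.cumsum(resp)
    )


def phase_window(env, phase: str) -> tuple[date, date] | None:
    """Return (start, end) dates of ``phase`` for an environment, if observed."""
    start_name, end_name = PHASE_BOUNDS[phase]
    start = getattr(env, start_name)
    end = getattr(env, end_name)
    if start is None or end is None:
        return None
    return start, end


def phase_duration(env, phase: str) -> int | None:
    """Observed whole-day duration of ``phase``, or None if unobserved."""
    win = phase_window(env, phase)
    if win is None:
        return None
    return (win[1] - win[0]).days
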