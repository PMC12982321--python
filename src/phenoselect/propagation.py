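"""Root-sum-of-squares propagation of scenario-data uncertainty.

Per covariate, the discrepancy between observed weather and a scenario
ensemble over a shared reference period is measured as an RMSE on the
min/max-standardized scale (pooled minimum -> 0, pooled maximum -> 1),
averaged over simulations.  For an additive model over a covariate
subset, the combined error is the Euclidean norm

    eps_f = sqrt(eps_1^2 + ... + eps_n^2),

which assumes the per-covariate errors are uncorrelated and roughly
homoscedastic.  eps_f is monotone in the subset: adding a covariate can
never reduce the propagated uncertainty.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, ValidationError
from .io_covariates import ScenarioEnsemble


def covariate_scenario_rmse(
    obs: pd.DataFrame,
    ensemble: ScenarioEnsemble,
    covariate: str,
    reference_window: tuple[int, int] | None = None,
    rcm_average: bool = False,
) -> float:
    """Standardized obs-vs-simulation RMSE for one covariate.

    Observations and every simulation are standardized by the *pooled*
    min/max over the reference window, matched station by station and
    calendar day by calendar day; per-simulation RMSEs are averaged
    uniformly over simulations (or within-then-across RCMs when
    ``rcm_average`` is set).
    """
    if reference_window is None:
        reference_window = ensemble.reference_window
    lo_year, hi_year = reference_window

    def ref_slice(df: pd.DataFrame) -> pd.DataFrame:
        years = pd.to_datetime(df["date"]).dt.year
        out = df[(years >= lo_year) & (years <= hi_year)]
        return out.set_index(["station_id", "date"])[[covariate]]

    obs_ref = ref_slice(obs)
    if obs_ref.empty:
        raise IntegrityError("observations do not cover the reference window")

    sims = []
    for sim in ensemble.simulations:
        s = ref_slice(sim.weather)
        joined = obs_ref.join(s, how="inner", lsuffix="_obs", rsuffix="_sim").dropna()
        if joined.empty:
            raise IntegrityError(
                f"simulation {sim.simulation_id} shares no reference days with "
                "the observations"
            )
        sims.append((sim.rcm_id, joined))

    pooled = np.concatenate(
        [obs_ref[covariate].dropna().to_numpy()]
        + [j[f"{covariate}_sim"].to_numpy() for _, j in sims]
    )
    lo, hi = float(np.min(pooled)), float(np.max(pooled))
    if not hi > lo:
        raise IntegrityError(f"covariate {covariate!r} is constant over the pool")
    per_sim: list[tuple[str, float]] = []
    for rcm, j in sims:
        o = (j[f"{covariate}_obs"].to_numpy() - lo) / (hi - lo)
        s = (j[f"{covariate}_sim"].to_numpy() - lo) / (hi - lo)
        per_sim.append((rcm, float(np.sqrt(np.mean((s - o) ** 2)))))
    if rcm_average:
        by_rcm: dict[str, list[float]] = {}
        for rcm, v in per_sim:
            by_rcm.setdefault(rcm, []).append(v)
        return float(np.mean([np.mean(v) for v in by_rcm.values()]))
    return float(np.mean([v for _, v in per_sim]))


def propagate_rss(errors: Sequence[float]) -> float:
    """Euclidean norm of per-covariate standardized errors."""
    if not 1 <= len(errors) <= 7:
        raise ValidationError("between 1 and 7 error terms expected")
    if any(e < 0 for e in errors):
        raise ValidationError("error terms must be non-negative")
    return math.sqrt(sum(float(e) ** 2 for e in errors))


def propagate_grid(
    errors: Mapping[str, float],
    subsets: Sequence[Sequence[str]],
) -> dict[str, float]:
    """Propagated uncertainty for every covariate subset, keyed by subset id."""
    out: dict[str, float] = {}
    for subset in subsets:
        missing = [c for c in subset if c not in errors]
        if missing:
            raise ConfigurationError(
                f"no scenario error for covariate(s) {missing}"
            )
        key = "+".join(sorted(subset))
        out[key] = propagate_rss([errors[c] for c in subset])
    return out
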