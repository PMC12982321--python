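"""Seeded simulation experiments on synthetic ground-truth bundles.

These are the package's standard validation experiments: cardinal
parameter recovery, an end-to-end calibrate/fit/select run, the
selection-logic contrasts between ground-truth and climate-scenario
model selection, and projection sanity checks (stationary vs. imposed
warming).  Each returns a plain dict of computed quantities so the test
suite and reporting scripts share one implementation.

Problem sizes are chosen to make each experiment informative at
single-workstation scale; docs/methods.md records them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationConfig,
    calibrate_covariate,
    fit_drc_two_step,
    prepare_phase_data,
)
from .composite import fit_model_grid
from .io_covariates import split_environments, stratified_split
from .projection import project_periods
from .selection import (
    median_phase_starts,
    select_max_cs,
    select_max_gt,
    select_opt,
)
from .synthetic import (
    ScenarioConfig,
    SyntheticConfig,
    generate_bundle,
    recovery_config,
    three_covariate_truth,
)
from .weather_index import WeatherIndex

TRUE_CARDINALS = {"psi_base": 0.0, "psi_opt": 25.0, "psi_max": 35.0}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def recovery_experiment(seed: int, n_replicates: int = 20) -> dict:
    """Refit the generating cardinal-temperature curve on fresh bundles.

    Per replicate (~500 environments, 2-day duration noise) a single
    two-step fit is run on the summer phase (identifies the optimum) and
    on the spring phase (identifies the base temperature).  Reports the
    median absolute errors against the true cardinals (25 and 0 deg C).
    """
    opt_errors, base_errors = [], []
    for rep_seed in _spawn_seeds(seed, n_replicates):
        bundle = generate_bundle(recovery_config(rep_seed), with_ensemble=False)
        wi = WeatherIndex(bundle.weather)
        config = CalibrationConfig(seed=rep_seed)
        summer = prepare_phase_data(
            bundle.environments, wi, "tas", "heading-senescence"
        )
        params = fit_drc_two_step(summer, "wang_engel", config)
        opt_errors.append(abs(params["psi_opt"] - TRUE_CARDINALS["psi_opt"]))
        spring = prepare_phase_data(
            bundle.environments, wi, "tas", "jointing-heading"
        )
        params = fit_drc_two_step(spring, "wang_engel", config)
        base_errors.append(abs(params["psi_base"] - TRUE_CARDINALS["psi_base"]))
    return {
        "n_replicates": n_replicates,
        "n_environments": 500,
        "psi_opt_median_abs_error": float(np.median(opt_errors)),
        "psi_base_median_abs_error": float(np.median(base_errors)),
    }


def end_to_end_max_gt(seed: int, ensemble_runs: int = 5) -> dict:
    """Full pipeline on a three-covariate truth: calibrate every candidate
    family per covariate, fit the subset grid, select by ground truth.

    Returns the winning model's validation RMSE and its ratio to the
    generator's 2-day duration-noise SD.
    """
    noise_sd = 2.0
    cfg = SyntheticConfig(
        n_stations=8, n_years=16, seed=seed, truth=three_covariate_truth(),
        duration_noise_sd=noise_sd,
    )
    bundle = generate_bundle(cfg, with_ensemble=False)
    wi = WeatherIndex(bundle.weather)
    phase = "jointing-heading"
    assignment = stratified_split(bundle.environments, 0.20, seed=seed)
    train, val = split_environments(bundle.environments, assignment)
    calib = CalibrationConfig(seed=seed, ensemble_runs=ensemble_runs)
    drc_map = {}
    for covariate in ("tas", "GR", "RH"):
        winner, _ = calibrate_covariate(train, wi, covariate, phase, calib)
        drc_map[covariate] = winner.spec
    grid = fit_model_grid(train, wi, drc_map, phase)
    profile, outcome = select_max_gt(grid, val, wi, horizon=150)
    rmse = profile.entries[outcome.complexity].rmse
    return {
        "n_environments": len(bundle.environments),
        "n_models": len(grid),
        "winning_complexity": outcome.complexity,
        "validation_rmse_days": float(rmse),
        "rmse_over_noise_sd": float(rmse / noise_sd),
    }


def _selection_run(seed: int, scenario: ScenarioConfig) -> tuple[int, int, int, dict]:
    cfg = SyntheticConfig(
        n_stations=4, n_years=12, seed=seed, truth=three_covariate_truth(),
        scenario=scenario,
    )
    bundle = generate_bundle(cfg)
    wi = WeatherIndex(bundle.weather)
    phase = "jointing-heading"
    drc_map = dict(bundle.truth[phase].drcs)
    assignment = stratified_split(bundle.environments, 0.25, seed=seed)
    train, val = split_environments(bundle.environments, assignment)
    grid = fit_model_grid(train, wi, drc_map, phase)
    profile_gt, out_gt = select_max_gt(grid, val, wi, horizon=120)
    by_id = {m.model_id: m for m in grid}
    best = {k: by_id[e.model_id] for k, e in profile_gt.entries.items()}
    starts = median_phase_starts(bundle.environments)
    profile_cs, out_cs = select_max_cs(best, wi, bundle.ensemble, starts, horizon=120)
    out_opt = select_opt(profile_gt, out_gt, profile_cs, out_cs)
    return out_gt.complexity, out_cs.complexity, out_opt.complexity, {
        "rmse_cs": {k: profile_cs.rmse(k) for k in profile_cs.entries},
    }


def zero_bias_selection(seed: int) -> dict:
    """With simulations identical to observations, scenario selection sees
    zero error everywhere and the compromise reduces to the ground-truth
    winner."""
    k_gt, k_cs, k_opt, extra = _selection_run(seed, ScenarioConfig(n_simulations=4))
    return {
        "max_cs_rmse_max": float(max(extra["rmse_cs"].values())),
        "max_gt_complexity": k_gt,
        "max_cs_complexity": k_cs,
        "opt_complexity": k_opt,
        "opt_equals_max_gt": int(k_opt == k_gt),
        "opt_inside_interval": int(min(k_gt, k_cs) <= k_opt <= max(k_gt, k_cs)),
    }


NOISY_SCENARIO_SD = {"tas": 1.5, "GR": 200.0, "RH": 8.0}


def noisy_selection_experiment(seed: int, n_replicates: int = 20) -> dict:
    """Independent per-covariate scenario noise: scenario-driven selection
    should not prefer more covariates than ground-truth selection."""
    results = []
    for rep_seed in _spawn_seeds(seed, n_replicates):
        scenario = ScenarioConfig(n_simulations=4, noise_sd=dict(NOISY_SCENARIO_SD))
        k_gt, k_cs, k_opt, _ = _selection_run(rep_seed, scenario)
        results.append((k_gt, k_cs, k_opt))
    frac = float(np.mean([k_cs <= k_gt for k_gt, k_cs, _ in results]))
    inside = all(
        min(k_gt, k_cs) <= k_opt <= max(k_gt, k_cs) for k_gt, k_cs, k_opt in results
    )
    return {
        "n_replicates": n_replicates,
        "cs_complexity_le_gt_fraction": frac,
        "opt_always_inside_interval": int(inside),
    }


def _projection_run(seed: int, trend_per_year: float, n_simulations: int = 20) -> pd.DataFrame:
    cfg = SyntheticConfig(
        n_stations=2, n_years=30, start_year=2000, seed=seed,
        scenario=ScenarioConfig(
            n_simulations=n_simulations,
            trend_per_year=trend_per_year,
            noise_sd={"tas": 0.5},
            projection_end_year=2090,
        ),
    )
    bundle = generate_bundle(cfg)
    wi = WeatherIndex(bundle.weather)
    models = {
        phase: fit_model_grid(bundle.environments, wi, dict(truth.drcs), phase)[0]
        for phase, truth in bundle.truth.items()
    }
    summary = project_periods(
        models, bundle.ensemble,
        periods={"reference": (2001, 2029), "mid": (2031, 2060),
                 "late": (2061, 2089)},
    )
    preds = summary.predictions.copy()
    preds["heading_das"] = (
        pd.to_datetime(preds["heading"]) - pd.to_datetime(preds["sowing"])
    ).dt.days
    return preds


def _per_sim_period_median(preds: pd.DataFrame, lo: int, hi: int) -> pd.Series:
    window = preds[(preds["harvest_year"] >= lo) & (preds["harvest_year"] <= hi)]
    return window.groupby("simulation_id")["heading_das"].median()


def stationary_projection_experiment(seed: int) -> dict:
    """Without a trend, distant 30-year periods should agree to sampling noise."""
    preds = _projection_run(seed, trend_per_year=0.0)
    mid = _per_sim_period_median(preds, 2031, 2060)
    late = _per_sim_period_median(preds, 2061, 2089)
    diff = (late - mid).dropna()
    return {
        "n_simulations": len(diff),
        "median_abs_period_shift_days": float(diff.abs().median()),
    }


def warming_projection_experiment(seed: int, trend_per_year: float = 0.04) -> dict:
    """An imposed warming trend must pull heading earlier in the late period."""
    preds = _projection_run(seed, trend_per_year=trend_per_year)
    ref = _per_sim_period_median(preds, 2001, 2029)
    late = _per_sim_period_median(preds, 2061, 2089)
    diff = (late - ref).dropna()
    return {
        "n_simulations": len(diff),
        "earlier_fraction": float((diff < 0).mean()),
        "median_shift_days": float(diff.median()),
    }
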