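"""Composite binomial-logit models: enumeration, design, fit, ROC, chaining."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import phenoselect as ps
from phenoselect.composite import (
    CompositeModel,
    build_design,
    chain_phases,
    enumerate_combinations,
    evaluate_model,
    fit_composite,
    fit_model_grid,
    predict_phase_end,
    roc_threshold,
    subset_id,
    with_threshold,
)
from phenoselect.drc import DRCSpec
from phenoselect.errors import (
    ConfigurationError,
    EvaluationError,
    FitError,
    ValidationError,
)

SEVEN = list(ps.MODEL_COVARIATES)


class TestEnumeration:
    def test_seven_covariates_yield_127_subsets(self):
        assert len(enumerate_combinations(SEVEN)) == 127

    @pytest.mark.parametrize("k,expected", [(1, 1), (3, 7), (5, 31)])
    def test_power_set_minus_empty(self, k, expected):
        assert len(enumerate_combinations(SEVEN[:k])) == expected

    def test_ordering_by_size_then_lexicographic(self):
        subs = enumerate_combinations(["b", "a", "c"])
        assert subs[:3] == [("a",), ("b",), ("c",)]
        assert subs[3] == ("a", "b")
        assert subs[-1] == ("a", "b", "c")

    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_combinations(["tas", "tas"])


@pytest.fixture(scope="module")
def true_drc_map(multi_bundle_mod):
    truth = multi_bundle_mod.truth["jointing-heading"]
    return dict(truth.drcs)


@pytest.fixture(scope="module")
def multi_bundle_mod():
    from phenoselect.synthetic import SyntheticConfig, three_covariate_truth

    cfg = SyntheticConfig(
        n_stations=6, n_years=12, seed=20240902, truth=three_covariate_truth()
    )
    return ps.generate_bundle(cfg, with_ensemble=False)


@pytest.fixture(scope="module")
def spring_design(multi_bundle_mod, true_drc_map):
    wi = ps.WeatherIndex(multi_bundle_mod.weather)
    return build_design(
        multi_bundle_mod.environments, wi, true_drc_map, "jointing-heading"
    )


class TestBuildDesign:
    def test_buffer_balances_classes_per_environment(self, multi_bundle_mod,
                                                     true_drc_map):
        env = multi_bundle_mod.environments[0]
        wi = ps.WeatherIndex(multi_bundle_mod.weather)
        design = build_design([env], wi, true_drc_map, "jointing-heading")
        dur = (env.heading - env.jointing).days
        assert len(design) == 2 * dur
        assert (design["label"] == 0).sum() == dur
        assert (design["label"] == 1).sum() == dur

    def test_constant_optimum_gives_arithmetic_dose_sequence(self, flat_weather):
        env = ps.PhenologyEnvironment(
            station_id="S1", harvest_year=2000,
            jointing=date(2000, 4, 1), heading=date(2000, 4, 11),
        )
        spec = DRCSpec("wang_engel", "tas", "jointing-heading",
                       {"psi_base": 0.0, "psi_opt": 25.0, "psi_max": 35.0, "r": 1.0})
        design = build_design([env], ps.WeatherIndex(flat_weather),
                              {"tas": spec}, "jointing-heading")
        np.testing.assert_allclose(
            design["Z_tas"].to_numpy(), np.arange(1, 21, dtype=float), rtol=1e-12
        )

    def test_two_environment_design_matches_day_loop(self, multi_bundle_mod,
                                                     true_drc_map):
        envs = multi_bundle_mod.environments[:2]
        wi = ps.WeatherIndex(multi_bundle_mod.weather)
        design = build_design(envs, wi, true_drc_map, "jointing-heading")
        # hand-build rows for the first environment and covariate tas
        env = envs[0]
        spec = true_drc_map["tas"]
        dur = (env.heading - env.jointing).days
        z, acc = [], 0.0
        for d in range(2 * dur):
            x = wi.window(env.station_id, "tas", env.jointing + timedelta(days=d), 1)[0]
            acc += float(spec.response(x))
            z.append(acc)
        got = design[design["harvest_year"] == env.harvest_year]
        got = got[got["station_id"] == env.station_id]["Z_tas"].to_numpy()[: 2 * dur]
        np.testing.assert_allclose(got, z, rtol=1e-10)


class TestFitComposite:
    def test_probability_crosses_half_near_single_dose_threshold(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 20, 600)
        labels = (z + rng.normal(0, 1.0, 600) > 10).astype(int)
        design = pd.DataFrame({"Z_tas": z, "label": labels})
        model = fit_composite(design, ("tas",), {"tas": _dummy_spec()}, "jointing-heading")
        crossing = -model.intercept / model.coefficients["tas"]
        assert abs(crossing - 10.0) < 1.0

    def test_duplicated_rows_leave_coefficients_unchanged(self, spring_design,
                                                          true_drc_map):
        m1 = fit_composite(spring_design, ("tas", "GR"), true_drc_map,
                           "jointing-heading")
        doubled = pd.concat([spring_design, spring_design], ignore_index=True)
        m2 = fit_composite(doubled, ("tas", "GR"), true_drc_map, "jointing-heading")
        assert m1.intercept == pytest.approx(m2.intercept, rel=1e-6)
        for c in m1.covariates:
            assert m1.coefficients[c] == pytest.approx(m2.coefficients[c], rel=1e-6)

    def test_absent_covariate_is_fit_error(self, spring_design, true_drc_map):
        with pytest.raises(FitError):
            fit_composite(spring_design, ("SPI",), true_drc_map, "jointing-heading")

    def test_single_class_is_fit_error(self, true_drc_map):
        design = pd.DataFrame({"Z_tas": [1.0, 2.0, 3.0], "label": [1, 1, 1]})
        with pytest.raises(FitError):
            fit_composite(design, ("tas",), true_drc_map, "jointing-heading")

    def test_nested_models_never_lose_likelihood(self, spring_design, true_drc_map):
        import statsmodels.api as sm

        y = spring_design["label"].to_numpy(dtype=float)

        def llf(cols):
            X = sm.add_constant(spring_design[cols].to_numpy(dtype=float))
            return sm.GLM(y, X, family=sm.families.Binomial()).fit().llf

        assert llf(["Z_tas", "Z_GR"]) >= llf(["Z_tas"]) - 1e-6
        assert llf(["Z_tas", "Z_GR", "Z_RH"]) >= llf(["Z_tas", "Z_GR"]) - 1e-6


def _dummy_spec():
    return DRCSpec("wang_engel", "tas", "jointing-heading",
                   {"psi_base": 0.0, "psi_opt": 25.0, "psi_max": 35.0, "r": 1.0})


class TestROCThreshold:
    def test_perfect_separation_midpoint(self):
        tau = roc_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert tau == pytest.approx(0.5)

    def test_uninformative_labels_warn(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.3, 0.7, 40)
        labels = np.array([0, 1] * 20)
        # label-independent probabilities: threshold exists but J ~ 0
        with pytest.warns(UserWarning, match="J ~ 0"):
            roc_threshold(np.repeat(p[:2], 20), labels)

    def test_matches_exhaustive_search_on_toy_set(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 20)
        y = (p + rng.normal(0, 0.3, 20) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            y[0], y[-1] = 0, 1
        tau = roc_threshold(p, y)
        # brute force over a fine threshold grid
        best_j, best_t = -np.inf, None
        for t in np.linspace(1e-6, 1 - 1e-6, 20001):
            pred = p >= t
            j = pred[y == 1].mean() + (~pred[y == 0]).mean() - 1.0
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        pred = p >= tau
        j_tau = pred[y == 1].mean() + (~pred[y == 0]).mean() - 1.0
        assert j_tau == pytest.approx(best_j, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            roc_threshold([0.2, 0.8], [1, 1])


@pytest.fixture(scope="module")
def refit_model(spring_design, true_drc_map):
    model = fit_composite(spring_design, ("tas", "GR", "RH"), true_drc_map,
                          "jointing-heading")
    return with_threshold(model, spring_design)


class TestPrediction:
    def test_self_consistent_duration_recovery(self, refit_model, multi_bundle_mod):
        wi = ps.WeatherIndex(multi_bundle_mod.weather)
        errors = []
        for env in multi_bundle_mod.environments[:10]:
            end, dur = predict_phase_end(
                refit_model, wi, env.station_id, env.jointing, 120
            )
            errors.append(dur - (env.heading - env.jointing).days)
        # observation noise SD is 2 days; the refit model should track it
        assert np.median(np.abs(errors)) <= 4.0

    def test_unreachable_threshold_censors(self, refit_model, multi_bundle_mod):
        wi = ps.WeatherIndex(multi_bundle_mod.weather)
        frozen = CompositeModel(
            phase=refit_model.phase,
            covariates=refit_model.covariates,
            drc_map=refit_model.drc_map,
            intercept=refit_model.intercept,
            coefficients=refit_model.coefficients,
            decision_threshold=1.0 - 1e-12,
        )
        env = multi_bundle_mod.environments[0]
        end, dur = predict_phase_end(frozen, wi, env.station_id, env.jointing, 30)
        assert end is None and np.isnan(dur)

    def test_zero_coefficient_covariates_do_not_change_prediction(
        self, spring_design, true_drc_map, multi_bundle_mod
    ):
        base = with_threshold(
            fit_composite(spring_design, ("tas",), true_drc_map, "jointing-heading"),
            spring_design,
        )
        padded = CompositeModel(
            phase=base.phase,
            covariates=("GR", "tas"),
            drc_map={"tas": true_drc_map["tas"], "GR": true_drc_map["GR"]},
            intercept=base.intercept,
            coefficients={"tas": base.coefficients["tas"], "GR": 0.0},
            decision_threshold=base.decision_threshold,
        )
        wi = ps.WeatherIndex(multi_bundle_mod.weather)
        env = multi_bundle_mod.environments[3]
        assert predict_phase_end(base, wi, env.station_id, env.jointing, 120) == \
            predict_phase_end(padded, wi, env.station_id, env.jointing, 120)


@pytest.fixture(scope="module")
def chain_models(multi_bundle_mod):
    wi = ps.WeatherIndex(multi_bundle_mod.weather)
    models = {}
    for phase, truth in multi_bundle_mod.truth.items():
        grid = fit_model_grid(
            multi_bundle_mod.environments, wi, dict(truth.drcs), phase
        )
        models[phase] = grid[-1]  # the full-covariate model of this phase
    return models


class TestChaining:
    def test_end_to_end_dates_close_to_generated_truth(self, chain_models,
                                                       multi_bundle_mod):
        wi = ps.WeatherIndex(multi_bundle_mod.weather)
        errs = []
        for env in multi_bundle_mod.environments[:8]:
            pred = chain_phases(chain_models, wi, env.station_id, env.sowing)
            for stage in ("emergence", "jointing", "heading", "senescence"):
                got, true = pred[stage], getattr(env, stage)
                assert got is not None
                errs.append(abs((got - true).days))
        # refit on its own noisy generator: errors on the order of the
        # 2-day observation noise, compounded over four chained phases
        assert np.median(errs) <= 8.0

    def test_censoring_propagates_to_all_later_stages(self, chain_models,
                                                      multi_bundle_mod):
        wi = ps.WeatherIndex(multi_bundle_mod.weather)
        env = multi_bundle_mod.environments[0]
        frozen = dict(chain_models)
        first = frozen["sowing-emergence"]
        frozen["sowing-emergence"] = CompositeModel(
            phase=first.phase, covariates=first.covariates, drc_map=first.drc_map,
            intercept=first.intercept, coefficients=first.coefficients,
            decision_threshold=1.0 - 1e-12,
        )
        pred = chain_phases(frozen, wi, env.station_id, env.sowing, default_horizon=30)
        assert all(pred[s] is None for s in ("emergence", "jointing", "heading",
                                             "senescence"))

    def test_missing_phase_model_is_configuration_error(self, chain_models,
                                                        multi_bundle_mod):
        wi = ps.WeatherIndex(multi_bundle_mod.weather)
        incomplete = {k: v for k, v in chain_models.items() if k != "jointing-heading"}
        with pytest.raises(ConfigurationError):
            chain_phases(incomplete, wi, "ST001", date(1995, 10, 30))

    def test_translation_equivariance_under_time_shifted_weather(
        self, chain_models, multi_bundle_mod
    ):
        k = 7
        shifted = multi_bundle_mod.weather.copy()
        shifted["date"] = pd.to_datetime(shifted["date"]) + pd.Timedelta(days=k)
        wi0 = ps.WeatherIndex(multi_bundle_mod.weather)
        wik = ps.WeatherIndex(shifted)
        env = multi_bundle_mod.environments[2]
        p0 = chain_phases(chain_models, wi0, env.station_id, env.sowing)
        pk = chain_phases(
            chain_models, wik, env.station_id, env.sowing + timedelta(days=k)
        )
        for stage in ("emergence", "jointing", "heading", "senescence"):
            assert (pk[stage] - p0[stage]).days == k


class TestEvaluateModel:
    def test_identity_scores_perfectly(self):
        m = evaluate_model([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert m["rmse"] == 0.0 and m["mae"] == 0.0
        assert m["pearson_r"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset(self):
        m = evaluate_model([13.0, 23.0, 33.0], [10.0, 20.0, 30.0])
        assert m["rmse"] == pytest.approx(3.0)
        assert m["mae"] == pytest.approx(3.0)
        assert m["pearson_r"] == pytest.approx(1.0)

    def test_five_pair_toy_matches_hand_arithmetic(self):
        pred = [12.0, 18.0, 25.0, 31.0, 44.0]
        obs = [10.0, 20.0, 24.0, 35.0, 40.0]
        m = evaluate_model(pred, obs)
        err = np.array(pred) - np.array(obs)
        assert m["rmse"] == pytest.approx(float(np.sqrt(np.mean(err**2))))
        assert m["mae"] == pytest.approx(float(np.mean(np.abs(err))))
        assert m["rmse"] >= m["mae"]

    def test_censored_pairs_excluded(self):
        m = evaluate_model([10.0, None, 30.0, 40.0], [10.0, 20.0, 30.0, 41.0])
        assert m["n"] == 3 and m["n_censored"] == 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(EvaluationError):
            evaluate_model([1.0, None], [1.0, 2.0])

    def test_constant_vector_leaves_correlation_undefined(self):
        m = evaluate_model([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert np.isnan(m["pearson_r"])


def test_grid_complete_for_three_covariates(multi_bundle_mod, true_drc_map):
    wi = ps.WeatherIndex(multi_bundle_mod.weather)
    grid = fit_model_grid(
        multi_bundle_mod.environments[:12], wi, true_drc_map, "jointing-heading"
    )
    assert len(grid) == 7
    assert sorted({m.complexity for m in grid}) == [1, 2, 3]
    assert all(m.decision_threshold is not None for m in grid)
    ids = [m.model_id for m in grid]
    assert len(set(ids)) == 7
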