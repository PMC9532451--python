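"""Behavioral model fitting: likelihood oracle, recovery, AIC, Wald tests."""

import numpy as np
import pytest

from neuropt import (BehaviorFit, BehaviorParams, ModelId,
                     choice_matrix_summary, compare_behavior_models,
                     fit_behavior, simulate_choices, wald_tests)
from neuropt.behavior import _nll_factory


def grid_search_nll(data, model, grids):
    """Independent oracle: exhaustive coarse grid over the free parameters."""
    nll, names = _nll_factory(ModelId(model), data)
    best = np.inf
    best_theta = None
    mesh = np.meshgrid(*[grids[n] for n in names], indexing="ij")
    thetas = np.column_stack([m.ravel() for m in mesh])
    for theta in thetas:
        v = nll(theta)
        if v < best:
            best, best_theta = v, theta
    return best, dict(zip(names, best_theta))


class TestFitBehavior:
    def test_matches_exhaustive_grid_oracle(self, small_pt2_choices):
        """The multi-start MLE is at least as good as a coarse grid search
        and lies within one grid step of the grid optimum."""
        grids = {"alpha": np.arange(0.2, 2.01, 0.15),
                 "delta": np.arange(0.2, 2.01, 0.15),
                 "gamma": np.arange(0.2, 2.01, 0.15),
                 "beta": np.arange(2.0, 30.0, 2.0)}
        for model in ("EV", "EU", "PT1", "PT2"):
            fit = fit_behavior(small_pt2_choices, model, n_starts=15, seed=0)
            nll_fn, names = _nll_factory(ModelId(model), small_pt2_choices)
            fit_nll = nll_fn(np.array([fit.params[n] for n in names]))
            grid_nll, grid_theta = grid_search_nll(small_pt2_choices, model,
                                                   grids)
            assert fit_nll <= grid_nll + 1e-6
            steps = {"alpha": 0.15, "delta": 0.15, "gamma": 0.15, "beta": 2.0}
            for name in names:
                if grids[name][0] < grid_theta[name] < grids[name][-1]:
                    assert abs(fit.params[name] - grid_theta[name]) <= \
                        steps[name] + 1e-9

    def test_ev_beta_recovery(self):
        data = simulate_choices(BehaviorParams(beta=10.0), "EV", 50_000,
                                seed=21)
        fit = fit_behavior(data, "EV", n_starts=8, seed=0)
        assert fit.converged
        assert fit.params["beta"] == pytest.approx(10.0, rel=0.05)

    def test_pt2_null_recovery_on_ev_data(self):
        """PT2 fit to EV-generated data: curvature parameters not
        significantly different from 1."""
        data = simulate_choices(BehaviorParams(beta=10.0), "EV", 20_000,
                                seed=33)
        fit = fit_behavior(data, "PT2", n_starts=10, seed=0)
        tests = {(w.parameter, w.null): w for w in wald_tests(fit)}
        for name in ("alpha", "delta", "gamma"):
            w = tests[(name, 1.0)]
            assert w.p_value > 0.05, f"{name} spuriously differs from 1"

    def test_aic_identity(self, small_pt2_choices):
        for model in ("EV", "EU", "PT1", "PT2"):
            fit = fit_behavior(small_pt2_choices, model, n_starts=5, seed=0)
            k = len(fit.free_names)
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)

    def test_standard_errors_positive(self, small_pt2_choices):
        fit = fit_behavior(small_pt2_choices, "EU", n_starts=5, seed=0)
        assert fit.converged
        for se in fit.std_errors.values():
            assert se > 0


class TestModelComparison:
    def test_pt2_selected_on_pt2_data(self, sun_params):
        data = simulate_choices(sun_params, "PT2", 20_000, seed=5)
        fits = compare_behavior_models(data, n_starts=8, seed=0)
        assert fits[0].model is ModelId.PT2
        assert fits[0].aic <= min(f.aic for f in fits[1:])

    def test_ev_favored_on_ev_data(self):
        """On EV-generated data the penalty dominates: EV wins the AIC
        ranking in most samples and is never significantly outperformed
        (the likelihood gain of richer models stays at chance level)."""
        from scipy.stats import chi2
        first = []
        for seed in (6, 16, 26):
            data = simulate_choices(BehaviorParams(beta=10.0), "EV", 20_000,
                                    seed=seed)
            fits = compare_behavior_models(data, n_starts=8, seed=0)
            by_model = {f.model: f for f in fits}
            first.append(fits[0].model)
            for model, extra in [(ModelId.EU, 1), (ModelId.PT1, 2),
                                 (ModelId.PT2, 3)]:
                lr = 2 * (by_model[model].loglik - by_model[ModelId.EV].loglik)
                assert lr < chi2.ppf(0.999, extra)
        assert first.count(ModelId.EV) >= 2

    def test_tiny_dataset_still_returns_ranking(self, sun_params):
        data = simulate_choices(sun_params, "PT2", 20, seed=7)
        fits = compare_behavior_models(data, n_starts=3, seed=0)
        assert len(fits) == 4
        assert all(np.isfinite(f.aic) for f in fits)


class TestWaldTests:
    def test_z_statistic_example(self):
        fit = BehaviorFit(ModelId.EU, {"alpha": 0.80, "delta": 1.0,
                                       "gamma": 1.0, "beta": 10.0},
                          {"alpha": 0.01735, "beta": 0.5}, -100.0, 204.0,
                          44_883, converged=True)
        tests = {(w.parameter, w.null): w for w in wald_tests(fit)}
        w = tests[("alpha", 1.0)]
        assert w.z == pytest.approx(-11.527, abs=0.01)
        assert w.p_value < 0.001
        assert w.df == 44_882

    def test_estimate_at_null_gives_p_one(self):
        fit = BehaviorFit(ModelId.EU, {"alpha": 1.0, "delta": 1.0,
                                       "gamma": 1.0, "beta": 10.0},
                          {"alpha": 0.02, "beta": 0.5}, -10.0, 24.0, 1000,
                          converged=True)
        tests = {(w.parameter, w.null): w for w in wald_tests(fit)}
        assert tests[("alpha", 1.0)].z == 0.0
        assert tests[("alpha", 1.0)].p_value == pytest.approx(1.0)

    def test_zero_se_reported_undefined(self):
        fit = BehaviorFit(ModelId.EU, {"alpha": 0.9, "delta": 1.0,
                                       "gamma": 1.0, "beta": 10.0},
                          {"alpha": 0.0, "beta": 0.5}, -10.0, 24.0, 1000,
                          converged=True)
        tests = {(w.parameter, w.null): w for w in wald_tests(fit)}
        assert np.isnan(tests[("alpha", 1.0)].z)

    def test_nonconverged_fit_rejected(self):
        fit = BehaviorFit(ModelId.EV, {"alpha": 1.0, "delta": 1.0,
                                       "gamma": 1.0, "beta": 0.0},
                          {}, -np.inf, np.inf, 100, converged=False)
        with pytest.raises(ValueError):
            wald_tests(fit)


class TestChoiceMatrix:
    def test_deterministic_chooser_splits_at_diagonal(self):
        params = BehaviorParams(beta=500.0)
        data = simulate_choices(params, "EV", 40_000, seed=8)
        mat = choice_matrix_summary(data).to_numpy()
        above = [mat[i, j] for i in range(10) for j in range(10)
                 if j > i and np.isfinite(mat[i, j])]
        below = [mat[i, j] for i in range(10) for j in range(10)
                 if j < i and np.isfinite(mat[i, j])]
        assert np.mean(above) > 0.95
        assert np.mean(below) < 0.05

    def test_random_chooser_is_flat(self):
        data = simulate_choices(BehaviorParams(beta=0.0), "EV", 50_000, seed=9)
        mat = choice_matrix_summary(data).to_numpy()
        cells = mat[np.isfinite(mat)]
        # sparse corner bins (few grid products above 0.9) are noisy, so
        # check the distribution of cells, not the extremes
        assert abs(np.nanmean(cells) - 0.5) < 0.02
        assert np.nanmedian(np.abs(cells - 0.5)) < 0.05

    def test_left_right_swap_transposes_to_complement(self, sun_params):
        from neuropt import ChoiceDataset
        data = simulate_choices(sun_params, "PT2", 30_000, seed=10)
        t = data.trials
        swapped = t.rename(columns={"p_left": "p_right", "p_right": "p_left",
                                    "m_left": "m_right", "m_right": "m_left"})
        swapped = swapped.assign(chose_right=1 - swapped["chose_right"])
        mat = choice_matrix_summary(data).to_numpy()
        mat_sw = choice_matrix_summary(ChoiceDataset(swapped)).to_numpy()
        both = np.isfinite(mat) & np.isfinite(mat_sw.T)
        assert np.allclose(mat[both], 1.0 - mat_sw.T[both], atol=1e-12)
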