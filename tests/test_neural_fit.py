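"""Neural NLS fits: exact noiseless recovery, brute-force oracle, AIC ladder."""

import numpy as np
import pytest

from neuropt import (ModelId, NeuronGroundTruth, compare_region,
                     fit_all_models, fit_signal, simulate_neuron)
from neuropt.neural_fit import neural_aic


def brute_force_sse(sig, model, step=0.1, lo=0.1, hi=4.0):
    """Oracle: dense grid over the nonlinear parameters with (g, b) by
    closed-form least squares at every grid point.

    Exploits the few unique p and m levels: the utility factor depends
    only on (alpha, m) and the weight factor only on (delta, gamma, p),
    so the trial design X is an outer product of small tables.
    """
    p = sig.trials["p"].to_numpy(float)
    m = sig.trials["m"].to_numpy(float)
    y = sig.trials["rate"].to_numpy(float)
    grid = np.arange(lo, hi + step / 2, step)
    up, pinv = np.unique(p, return_inverse=True)
    um, minv = np.unique(m, return_inverse=True)
    model = ModelId(model)
    U = um[None, :] ** grid[:, None]                       # (A, #m)
    if model is ModelId.EU:
        X = up[pinv][None, :] * U[:, minv]                 # (A, n)
    elif model is ModelId.PT1:
        W = np.exp(-((-np.log(up))[None, :] ** grid[:, None]))  # (G, #p)
        X = (U[:, None, :][:, :, minv] * W[None, :, pinv]).reshape(-1, len(y))
    elif model is ModelId.PT2:
        dd, gg = np.meshgrid(grid, grid, indexing="ij")
        W = np.exp(-dd.ravel()[:, None]
                   * (-np.log(up))[None, :] ** gg.ravel()[:, None])  # (DG, #p)
        X = (U[:, None, :][:, :, minv] * W[None, :, pinv]).reshape(-1, len(y))
    else:
        raise ValueError("EV has no nonlinear parameter to grid over")
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    sxy = Xc @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = syy - np.where(sxx > 0, sxy**2 / np.maximum(sxx, 1e-300), 0.0)
    return float(np.min(sse))


class TestFitSignal:
    def test_noiseless_pt2_exact_recovery(self, c1_truth):
        from dataclasses import replace
        gt = replace(c1_truth, noise_scale=0.0)
        sig = simulate_neuron(gt, 1, seed=0)
        fit = fit_signal(sig, "PT2", n_starts=30, seed=0)
        assert fit.sse < 1e-10
        assert fit.b == pytest.approx(gt.b, abs=1e-4)
        assert fit.g == pytest.approx(gt.g, abs=1e-4)
        assert fit.alpha == pytest.approx(gt.alpha, abs=1e-4)
        assert fit.delta == pytest.approx(gt.delta, abs=1e-4)
        assert fit.gamma == pytest.approx(gt.gamma, abs=1e-4)

    def test_multistart_matches_brute_force_grid(self):
        """On 20 random small signals the multi-start optimum is at least
        as good as a dense parameter grid with closed-form (g, b)."""
        rng = np.random.default_rng(12)
        for i in range(20):
            gt = NeuronGroundTruth(
                b=rng.uniform(-2, 8), g=rng.uniform(3, 12) * rng.choice([-1, 1]),
                alpha=rng.uniform(0.3, 2.5), delta=rng.uniform(0.3, 2.5),
                gamma=rng.uniform(0.3, 2.5))
            sig = simulate_neuron(gt, 1, seed=100 + i)
            for model in ("EU", "PT1", "PT2"):
                fit = fit_signal(sig, model, n_starts=40, seed=i)
                oracle = brute_force_sse(sig, model)
                assert fit.sse <= oracle + 1e-6 * (1 + oracle), \
                    f"signal {i}, {model}: {fit.sse} > grid {oracle}"

    def test_nested_sse_monotone(self, c1_truth):
        sig = simulate_neuron(c1_truth, 1, seed=3)
        sses = [fit_signal(sig, m, n_starts=40, seed=0).sse
                for m in ("EV", "EU", "PT1", "PT2")]
        for simpler, richer in zip(sses, sses[1:]):
            assert richer <= simpler + 1e-8

    def test_negative_coding_recovered_with_negative_gain(self):
        from dataclasses import replace
        gt = NeuronGroundTruth(b=10.6, g=-10.1, alpha=0.64, delta=1.30,
                               gamma=2.64, noise_scale=0.0)
        sig = simulate_neuron(gt, 1, seed=0)
        fit = fit_signal(sig, "PT2", n_starts=30, seed=0)
        assert fit.g == pytest.approx(-10.1, abs=1e-4)
        # curvature matches the mirrored positive-coding twin
        mirrored = simulate_neuron(replace(gt, g=10.1, b=-0.68), 1, seed=0)
        twin = fit_signal(mirrored, "PT2", n_starts=30, seed=0)
        assert fit.alpha == pytest.approx(twin.alpha, abs=1e-4)
        assert fit.gamma == pytest.approx(twin.gamma, abs=1e-4)

    def test_aic_sse_identity_and_r2_bound(self, c1_truth):
        sig = simulate_neuron(c1_truth, 1, seed=4)
        for model in ("EV", "EU", "PT1", "PT2"):
            fit = fit_signal(sig, model, n_starts=20, seed=0)
            assert fit.aic == pytest.approx(
                neural_aic(fit.sse, fit.n_trials, model))
            assert fit.r2 <= 1.0

    def test_too_few_trials_rejected(self, c1_truth):
        sig = simulate_neuron(c1_truth, 1, seed=5)
        sig.trials = sig.trials.head(10)
        with pytest.raises(ValueError):
            fit_signal(sig, "PT2")


class TestFitAllModels:
    def test_pt2_wins_on_strongly_curved_low_noise_signals(self):
        rng = np.random.default_rng(13)
        wins = 0
        n_sig = 12
        for i in range(n_sig):
            gt = NeuronGroundTruth(b=2.0, g=15.0, alpha=0.5, delta=2.0,
                                   gamma=2.5, noise_model="gaussian_rate",
                                   noise_scale=0.5)
            sig = simulate_neuron(gt, 1, seed=200 + i)
            _, best = fit_all_models(sig, n_starts=30, seed=i)
            wins += best is ModelId.PT2
        assert wins > n_sig / 2

    def test_ev_wins_modal_share_on_ev_signals(self):
        rng = np.random.default_rng(14)
        best_models = []
        for i in range(12):
            gt = NeuronGroundTruth(b=1.0, g=10.0)
            sig = simulate_neuron(gt, 1, seed=300 + i)
            _, best = fit_all_models(sig, n_starts=30, seed=i)
            best_models.append(best)
        counts = {m: best_models.count(m) for m in set(best_models)}
        assert max(counts, key=counts.get) is ModelId.EV


class TestCompareRegion:
    def _population_fits(self, gt_factory, n, seed0, n_starts=25):
        out = []
        for i in range(n):
            sig = simulate_neuron(gt_factory(i), 1, seed=seed0 + i)
            fits, _ = fit_all_models(sig, n_starts=n_starts, seed=i)
            out.append(fits)
        return out

    def test_pt2_population_yields_pt2_winner(self):
        fits = self._population_fits(
            lambda i: NeuronGroundTruth(b=2.0, g=15.0, alpha=0.5, delta=2.0,
                                        gamma=2.5,
                                        noise_model="gaussian_rate",
                                        noise_scale=0.5),
            n=15, seed0=400)
        cmp_ = compare_region(fits, "DS")
        assert cmp_.winner == "PT2"
        rung = cmp_.ladder.set_index("rung").loc["PT1-PT2"]
        assert rung["p"] < 0.05 and rung["mean_diff"] > 0

    def test_ev_population_never_prefers_complex_models(self):
        fits = self._population_fits(lambda i: NeuronGroundTruth(b=1.0, g=10.0),
                                     n=15, seed0=500)
        cmp_ = compare_region(fits, "VS")
        assert cmp_.winner in ("EV", "undetermined")

    def test_identical_aic_across_models_reports_no_difference(self):
        from neuropt.neural_fit import NeuralFit
        fits = {m: NeuralFit("n0", "cOFC", "e1", m, 1.0, 5.0, 1.0, 1.0, 1.0,
                             sse=10.0, r2=0.5, aic=42.0, n_trials=100,
                             converged=True)
                for m in (ModelId.EV, ModelId.EU, ModelId.PT1, ModelId.PT2)}
        cmp_ = compare_region([fits, fits], "cOFC")
        assert cmp_.winner == "undetermined"
        assert cmp_.ladder["mean_diff"].abs().max() < 1e-12
        assert cmp_.ladder["t"].isna().all()
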