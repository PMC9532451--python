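"""Maximum-likelihood fitting of valuation models to risky-choice data.

The choice rule is logistic random utility: P(right) = 1/(1+exp(-z)),
z = beta*(V_R - V_L), with V given by one of the four nested models
(EV, EU, PT1, PT2).  Fitting maximizes the Bernoulli log-likelihood
over the model's free valuation parameters plus beta, from multiple
random starts; models are compared by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import FREE_PARAMS, ModelId, aic, subjective_value
from .synthetic import ChoiceDataset

# box constraints used for every start and for the final optimum
PARAM_BOUNDS = {"alpha": (0.05, 5.0), "delta": (0.05, 5.0),
                "gamma": (0.05, 5.0), "beta": (0.0, 100.0)}
_BETA_START_RANGE = (0.5, 50.0)


@dataclass
class BehaviorFit:
    """One model's MLE on one choice dataset."""

    model: ModelId
    params: dict[str, float]          # always alpha/delta/gamma/beta; fixed entries = 1
    std_errors: dict[str, float]      # free parameters only
    loglik: float
    aic: float
    n_trials: int
    converged: bool
    n_starts: int = 0

    @property
    def free_names(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.model] + ("beta",)


@dataclass
class WaldTest:
    parameter: str
    null: float
    estimate: float
    se: float
    z: float
    df: int
    p_value: float


def _factorize(data: ChoiceDataset):
    """Map each side's lotteries to a shared unique-(p, m) table.

    The task grid has at most 100 distinct lotteries, so values are
    computed once per unique cue and scattered to trials by index.
    """
    t = data.trials
    pm = np.column_stack([
        np.concatenate([t["p_left"].to_numpy(float), t["p_right"].to_numpy(float)]),
        np.concatenate([t["m_left"].to_numpy(float), t["m_right"].to_numpy(float)]),
    ])
    uniq, inv = np.unique(pm, axis=0, return_inverse=True)
    n = len(t)
    return uniq[:, 0], uniq[:, 1], inv[:n], inv[n:], t["chose_right"].to_numpy(float)


def _nll_factory(model: ModelId, data: ChoiceDataset):
    up, um, i_left, i_right, y = _factorize(data)
    names = FREE_PARAMS[model] + ("beta",)

    def nll(theta: np.ndarray) -> float:
        kw = dict(alpha=1.0, delta=1.0, gamma=1.0)
        for name, val in zip(names, theta):
            kw[name] = float(val)
        beta = kw.pop("beta")
        v = subjective_value(model, up, um, **kw)
        z = beta * (v[i_right] - v[i_left])
        return float(np.sum(y * np.logaddexp(0.0, -z)
                            + (1.0 - y) * np.logaddexp(0.0, z)))

    return nll, names


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.maximum(np.abs(x), 1.0) * rel_step
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                hess[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[[i, j]] += [h[i], -h[j]]
                xmp[[i, j]] += [-h[i], h[j]]
                xmm[[i, j]] += [-h[i], -h[j]]
                hess[i, j] = hess[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * h[i] * h[j])
    return hess


def _standard_errors(nll, x: np.ndarray, names) -> dict[str, float]:
    """SEs from the observed-information inverse at the optimum."""
    try:
        hess = _numerical_hessian(nll, x)
        cov = np.linalg.inv(hess)
        var = np.diag(cov)
    except np.linalg.LinAlgError:
        return {n: float("nan") for n in names}
    se = np.sqrt(np.where(var > 0, var, np.nan))
    return dict(zip(names, se.tolist()))


def fit_behavior(data: ChoiceDataset, model: ModelId | str,
                 n_starts: int = 20, seed: int = 0) -> BehaviorFit:
    """Fit one valuation model by multi-start maximum likelihood.

    The first start is the neutral point (all curvature parameters 1,
    moderate beta); the rest are drawn log-uniform within the parameter
    bounds.  The best converged run is returned; standard errors come
    from the observed information at the optimum.
    """
    model = ModelId(model)
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    nll, names = _nll_factory(model, data)
    bounds = [PARAM_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)

    starts = [np.array([1.0 if n != "beta" else 5.0 for n in names])]
    for _ in range(n_starts - 1):
        s = []
        for n in names:
            lo, hi = PARAM_BOUNDS[n] if n != "beta" else _BETA_START_RANGE
            lo = max(lo, 1e-3)
            s.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        starts.append(np.array(s))

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    if best is None:
        params = dict(alpha=1.0, delta=1.0, gamma=1.0, beta=0.0)
        return BehaviorFit(model, params, {n: float("nan") for n in names},
                           float("-inf"), float("inf"), data.n_trials,
                           converged=False, n_starts=n_starts)

    params = dict(alpha=1.0, delta=1.0, gamma=1.0, beta=0.0)
    for n, v in zip(names, best.x):
        params[n] = float(v)
    loglik = -float(best.fun)
    k = len(names)  # free valuation parameters + beta
    se = _standard_errors(nll, best.x, names) if any_converged else {
        n: float("nan") for n in names}
    return BehaviorFit(model, params, se, loglik, aic(loglik, k),
                       data.n_trials, converged=any_converged,
                       n_starts=n_starts)


def wald_tests(fit: BehaviorFit, nulls=(0.0, 1.0)) -> list[WaldTest]:
    """Wald tests of each free parameter against the given null values.

    z = (estimate - null) / SE, referred to a t distribution with
    df = n_trials - 1 (the convention used for reporting fitted
    behavioral parameters).
    """
    if not fit.converged:
        raise ValueError("cannot test a non-converged fit")
    out = []
    df = fit.n_trials - 1
    for name in fit.free_names:
        est = fit.params[name]
        se = fit.std_errors.get(name, float("nan"))
        for null in nulls:
            if not np.isfinite(se) or se == 0:
                out.append(WaldTest(name, null, est, se, float("nan"), df,
                                    float("nan")))
                continue
            z = (est - null) / se
            p = 2.0 * stats.t.sf(abs(z), df)
            out.append(WaldTest(name, null, est, se, float(z), df, float(p)))
    return out


def compare_behavior_models(data: ChoiceDataset, n_starts: int = 20,
                            seed: int = 0) -> list[BehaviorFit]:
    """Fit EV, EU, PT1 and PT2; rank by AIC ascending, ties to fewer parameters."""
    fits = [fit_behavior(data, m, n_starts=n_starts, seed=seed)
            for m in (ModelId.EV, ModelId.EU, ModelId.PT1, ModelId.PT2)]
    return sorted(fits, key=lambda f: (f.aic, len(f.free_names)))


def choice_matrix_summary(data: ChoiceDataset, bin_width: float = 0.1) -> pd.DataFrame:
    """Right-choice frequency binned by (EV_left, EV_right).

    Expected values (p*m, which span (0, 1] on the task grid) are binned
    at ``bin_width``; empty cells are NaN.  Rows index the left option's
    EV bin, columns the right's.
    """
    t = data.trials
    ev_l = t["p_left"].to_numpy(float) * t["m_left"].to_numpy(float)
    ev_r = t["p_right"].to_numpy(float) * t["m_right"].to_numpy(float)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    il = np.clip(np.digitize(ev_l, edges, right=True) - 1, 0, n_bins - 1)
    ir = np.clip(np.digitize(ev_r, edges, right=True) - 1, 0, n_bins - 1)
    y = t["chose_right"].to_numpy(float)
    count = np.zeros((n_bins, n_bins))
    chosen = np.zeros((n_bins, n_bins))
    np.add.at(count, (il, ir), 1.0)
    np.add.at(chosen, (il, ir), y)
    with np.errstate(invalid="ignore"):
        freq = np.where(count > 0, chosen / np.maximum(count, 1), np.nan)
    labels = [f"{edges[i]:.1f}-{edges[i + 1]:.1f}" for i in range(n_bins)]
    return pd.DataFrame(freq, index=pd.Index(labels, name="ev_left"),
                        columns=pd.Index(labels, name="ev_right"))
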