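"""Nonlinear least-squares fits of valuation models to firing rates.

Each qualifying neuron-epoch is fit trial-by-trial with
R = g*w(p)*u(m) + b under the four nested models.  The gain g and
baseline b enter linearly, so they are profiled out exactly by ordinary
least squares at every evaluation of the nonlinear parameters (alpha,
delta, gamma), which are optimized from many random starts.  Model
comparison uses the Gaussian-likelihood AIC equivalent
n*log(SSE/n) + 2k with k = 2 (EV), 3 (EU), 4 (PT1), 5 (PT2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import FREE_PARAMS, ModelId, subjective_value
from .synthetic import NeuronSignal

logger = logging.getLogger(__name__)

NL_BOUNDS = (0.05, 5.0)  # alpha, delta, gamma
#: parameters counted in the neural AIC (g and b plus the nonlinear ones)
NEURAL_K = {ModelId.EV: 2, ModelId.EU: 3, ModelId.PT1: 4, ModelId.PT2: 5}
_MODEL_ORDER = (ModelId.EV, ModelId.EU, ModelId.PT1, ModelId.PT2)


@dataclass
class NeuralFit:
    neuron_id: str
    region: str
    epoch_id: str
    model: ModelId
    b: float
    g: float
    alpha: float
    delta: float
    gamma: float
    sse: float
    r2: float
    aic: float
    n_trials: int
    converged: bool

    def params(self) -> dict[str, float]:
        return {"b": self.b, "g": self.g, "alpha": self.alpha,
                "delta": self.delta, "gamma": self.gamma}


def neural_aic(sse: float, n: int, model: ModelId) -> float:
    """AIC up to an additive constant shared by all models on a signal."""
    return n * float(np.log(max(sse, 1e-300) / n)) + 2 * NEURAL_K[ModelId(model)]


def _profile_sse(model: ModelId, p, m, y, theta):
    """SSE with (g, b) solved by least squares given the nonlinear parameters."""
    kw = dict(alpha=1.0, delta=1.0, gamma=1.0)
    for name, val in zip(FREE_PARAMS[model], theta):
        kw[name] = float(val)
    x = subjective_value(model, p, m, **kw)
    A = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1]), kw


def fit_signal(sig: NeuronSignal, model: ModelId | str, n_starts: int = 100,
               seed: int = 0) -> NeuralFit:
    """Fit one model to one neuron-epoch by multi-start profiled NLS.

    Starts for the nonlinear parameters are drawn log-uniform in
    [0.05, 5] (plus the neutral point 1); the lowest-SSE converged run
    wins.  EV has no nonlinear parameter and reduces to a single linear
    solve.
    """
    model = ModelId(model)
    t = sig.trials
    if len(t) < 20:
        raise ValueError("neural fitting needs at least 20 trials")
    p = t["p"].to_numpy(float)
    m = t["m"].to_numpy(float)
    if len(np.unique(np.column_stack([p, m]), axis=0)) < 4:
        raise ValueError("neural fitting needs at least 4 distinct lotteries")
    y = t["rate"].to_numpy(float)
    names = FREE_PARAMS[model]
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))

    def finish(sse, g, b, kw, converged):
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        return NeuralFit(sig.neuron_id, sig.region, sig.epoch_id, model,
                         b, g, kw["alpha"], kw["delta"], kw["gamma"],
                         sse, r2, neural_aic(sse, n, model), n, converged)

    if not names:  # EV: purely linear
        sse, g, b, kw = _profile_sse(model, p, m, y, ())
        return finish(sse, g, b, kw, True)

    rng = np.random.default_rng(seed)
    objective = lambda th: _profile_sse(model, p, m, y, th)[0]
    starts = [np.ones(len(names))]
    lo, hi = NL_BOUNDS
    for _ in range(n_starts - 1):
        starts.append(np.exp(rng.uniform(np.log(lo), np.log(hi), len(names))))

    best_x, best_sse, converged = None, np.inf, False
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=[NL_BOUNDS] * len(names),
                                options={"ftol": 1e-12, "gtol": 1e-10,
                                         "maxiter": 500})
        if np.isfinite(res.fun) and res.fun < best_sse:
            best_sse, best_x = float(res.fun), res.x
            converged = converged or bool(res.success)
        elif res.success:
            converged = True
    if best_x is None:
        logger.warning("signal %s/%s: no converged %s run",
                       sig.neuron_id, sig.epoch_id, model.value)
        return finish(np.inf, np.nan, np.nan,
                      dict(alpha=1.0, delta=1.0, gamma=1.0), False)
    sse, g, b, kw = _profile_sse(model, p, m, y, best_x)
    return finish(sse, g, b, kw, converged)


def fit_all_models(sig: NeuronSignal, n_starts: int = 100,
                   seed: int = 0) -> tuple[dict[ModelId, NeuralFit], ModelId | None]:
    """Fit EV, EU, PT1 and PT2 to a signal; return fits and the AIC winner.

    Non-converged models are excluded from the comparison; ties go to
    the model with fewer parameters.
    """
    fits = {mod: fit_signal(sig, mod, n_starts=n_starts, seed=seed)
            for mod in _MODEL_ORDER}
    candidates = [(f.aic, NEURAL_K[mod], mod) for mod, f in fits.items()
                  if f.converged]
    best = min(candidates)[2] if candidates else None
    return fits, best


@dataclass
class RegionModelComparison:
    """Ladder of paired AIC tests for one region: EV-EU, EU-PT1, PT1-PT2."""

    region: str
    n_signals: int
    ladder: pd.DataFrame  # rung, mean_diff, t, df, p
    winner: str           # "EV", "EU", "PT1", "PT2" or "undetermined"


def compare_region(per_signal_fits: list[dict[ModelId, NeuralFit]],
                   region: str, alpha_level: float = 0.05) -> RegionModelComparison:
    """One-sample t-tests on per-signal AIC differences along the nesting ladder.

    A positive mean difference on a rung favors the more complex model.
    The winner is the most complex model whose rung (and no higher one)
    is significantly positive; if no rung is significant in either
    direction the comparison is undetermined.
    """
    usable = [f for f in per_signal_fits
              if all(f[mod].converged for mod in _MODEL_ORDER)]
    if len(usable) < 2:
        raise ValueError("need at least two fully fitted signals")
    aics = {mod: np.array([f[mod].aic for f in usable]) for mod in _MODEL_ORDER}
    rungs = [("EV-EU", aics[ModelId.EV] - aics[ModelId.EU]),
             ("EU-PT1", aics[ModelId.EU] - aics[ModelId.PT1]),
             ("PT1-PT2", aics[ModelId.PT1] - aics[ModelId.PT2])]
    rows = []
    for name, d in rungs:
        if np.allclose(d.std(ddof=1), 0.0):
            t_stat, p_val = (np.nan, np.nan) if np.allclose(d.mean(), 0.0) \
                else (np.inf * np.sign(d.mean()), 0.0)
        else:
            t_stat, p_val = stats.ttest_1samp(d, 0.0)
        rows.append({"rung": name, "mean_diff": float(d.mean()),
                     "t": float(t_stat), "df": len(d) - 1,
                     "p": float(p_val)})
    ladder = pd.DataFrame(rows)

    sig_pos = [(r["p"] < alpha_level) and (r["mean_diff"] > 0)
               if np.isfinite(r["p"]) else False for r in rows]
    sig_neg = [(r["p"] < alpha_level) and (r["mean_diff"] < 0)
               if np.isfinite(r["p"]) else False for r in rows]
    if sig_pos[2]:
        winner = "PT2"
    elif sig_pos[1]:
        winner = "PT1"
    elif sig_pos[0]:
        winner = "EU"
    elif any(sig_neg):
        winner = "EV"
    else:
        winner = "undetermined"
    return RegionModelComparison(region, len(usable), ladder, winner)


def fit_table(per_signal_fits: list[dict[ModelId, NeuralFit]],
              best: list[ModelId | None] | None = None) -> pd.DataFrame:
    """Per-signal parameter table (one row per signal x model).

    The same schema reads externally supplied fitted-parameter tables.
    """
    rows = []
    for i, fits in enumerate(per_signal_fits):
        b_mod = best[i] if best is not None else None
        for mod, f in fits.items():
            rows.append({"neuron_id": f.neuron_id, "region": f.region,
                         "epoch_id": f.epoch_id, "model": mod.value,
                         "b": f.b, "g": f.g, "alpha": f.alpha,
                         "delta": f.delta, "gamma": f.gamma, "sse": f.sse,
                         "r2": f.r2, "aic": f.aic,
                         "best_flag": int(mod == b_mod)})
    return pd.DataFrame(rows)
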