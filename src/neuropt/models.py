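"""Core valuation functions shared by the behavioral and neural models.

Four nested models of the subjective value V(p, m) of a lottery:

    EV   V = p * m
    EU   V = p * m**alpha
    PT1  V = exp(-(-log p)**gamma) * m**alpha
    PT2  V = exp(-delta * (-log p)**gamma) * m**alpha

PT1 is the one-parameter Prelec weighting, PT2 the two-parameter form;
PT2 collapses to PT1 at delta=1, PT1 to EU at gamma=1, EU to EV at
alpha=1.  Choices follow a logistic random-utility rule on the value
difference; neural firing follows R = g * w(p) * u(m) + b.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.special import expit


class ModelId(str, Enum):
    EV = "EV"
    EU = "EU"
    PT1 = "PT1"
    PT2 = "PT2"


#: free valuation parameters per model, excluding the choice gain beta
FREE_PARAMS: dict[ModelId, tuple[str, ...]] = {
    ModelId.EV: (),
    ModelId.EU: ("alpha",),
    ModelId.PT1: ("alpha", "gamma"),
    ModelId.PT2: ("alpha", "delta", "gamma"),
}


def n_free_params(model: ModelId, include_beta: bool = False) -> int:
    return len(FREE_PARAMS[ModelId(model)]) + int(include_beta)


def utility(m, alpha: float):
    """Power (constant relative risk attitude) utility u(m) = m**alpha.

    Concave (risk-averse) for alpha < 1, convex for alpha > 1.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("reward magnitude must be positive")
    if alpha <= 0:
        raise ValueError("utility curvature alpha must be positive")
    out = m**alpha
    return float(out) if out.ndim == 0 else out


def prelec_weight(p, delta: float, gamma: float):
    """Two-parameter Prelec probability weight w(p) = exp(-delta*(-log p)**gamma).

    delta = gamma = 1 is the identity; delta = 1 gives the one-parameter
    form.  Strictly increasing in p on (0, 1] with w(1) = 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("probability must lie in (0, 1]")
    if delta <= 0 or gamma <= 0:
        raise ValueError("Prelec parameters delta and gamma must be positive")
    out = np.exp(-delta * (-np.log(p)) ** gamma)
    return float(out) if out.ndim == 0 else out


def subjective_value(model, p, m, alpha: float = 1.0, delta: float = 1.0,
                     gamma: float = 1.0):
    """V(p, m) = w(p) * u(m) under the given model.

    Parameters not free in the model are ignored (fixed at 1).
    """
    model = ModelId(model)
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    if model is ModelId.EV:
        out = p * m
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("probability must lie in (0, 1]")
    elif model is ModelId.EU:
        out = p * utility(m, alpha)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("probability must lie in (0, 1]")
    elif model is ModelId.PT1:
        out = prelec_weight(p, 1.0, gamma) * utility(m, alpha)
    elif model is ModelId.PT2:
        out = prelec_weight(p, delta, gamma) * utility(m, alpha)
    else:  # pragma: no cover - Enum guards this
        raise ValueError(f"unknown model {model!r}")
    return float(out) if np.ndim(out) == 0 else out


def choice_prob(v_left, v_right, beta: float):
    """P(choose right) = 1 / (1 + exp(-beta * (vR - vL))).

    beta >= 0 scales choice stochasticity: 0 is random, large beta is
    near-deterministic value maximization.
    """
    if beta < 0:
        raise ValueError("choice gain beta must be nonnegative")
    z = beta * (np.asarray(v_right, dtype=float) - np.asarray(v_left, dtype=float))
    out = expit(z)
    return float(out) if out.ndim == 0 else out


def neural_response(model, p, m, b: float, g: float, alpha: float = 1.0,
                    delta: float = 1.0, gamma: float = 1.0):
    """Predicted firing rate R = g * w(p) * u(m) + b (spikes/s).

    Negative-coding (P-M-) neurons are represented by g < 0; R itself may
    be negative and is truncated only when realizing spike counts.
    """
    v = subjective_value(model, p, m, alpha=alpha, delta=delta, gamma=gamma)
    out = g * np.asarray(v, dtype=float) + b
    return float(out) if np.ndim(out) == 0 else out


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, -2*L + 2*k; lower is better."""
    if k < 1:
        raise ValueError("parameter count k must be at least 1")
    return -2.0 * loglik + 2.0 * k
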