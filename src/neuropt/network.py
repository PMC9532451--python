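"""Three-layer rate network reconstructing internal risk preferences.

Layer 1: each cluster j responds to a lottery with its PT2 surface
R_j = g_j*w(p)*u(m) + b_j (mean parameters).  Layer 2: responses are
summed with signs (+ for positive-coding clusters, - for the
negative-coding ones, inverting their anticorrelated signal) and passed
through a ReLU, giving a population subjective expected value
SEV(p, m) = max(0, sum_j s_j R_j).  Layer 3: choices between two
lotteries follow the logistic rule on the SEV difference with unit
gain.  Fitting PT2 to the simulated choices recovers the internal
utility curvature and probability weighting implied by the population
code; repetitions give their sampling distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorFit, fit_behavior
from .lotteries import grid_arrays
from .models import ModelId, neural_response
from .synthetic import ChoiceDataset


@dataclass(frozen=True)
class ClusterParams:
    b: float
    g: float
    alpha: float
    delta: float
    gamma: float

    @property
    def sign(self) -> int:
        """Subtractive clusters are those with negative mean gain."""
        return -1 if self.g < 0 else 1


@dataclass
class NetworkModel:
    """Cluster parameter sets feeding the signed-sum + ReLU aggregator.

    The choice layer uses beta = 1 exactly: the SEV difference is passed
    to the logistic untransformed.
    """

    clusters: list[ClusterParams]
    beta: float = 1.0

    @classmethod
    def from_means_table(cls, means: pd.DataFrame) -> "NetworkModel":
        return cls([ClusterParams(float(r["b"]), float(r["g"]),
                                  float(r["alpha"]), float(r["delta"]),
                                  float(r["gamma"]))
                    for _, r in means.iterrows()])


def sev_surface(net: NetworkModel, return_clip_fraction: bool = False):
    """Population SEV on the 100-lottery grid: ReLU of the signed cluster sum.

    Negative-gain clusters enter with a minus sign, which flips their
    anticorrelated response back into alignment with value.
    """
    gp, gm = grid_arrays()
    total = np.zeros(100)
    for c in net.clusters:
        r = neural_response(ModelId.PT2, gp, gm, c.b, c.g, c.alpha, c.delta,
                            c.gamma)
        total += c.sign * np.asarray(r)
    sev = np.clip(total, 0.0, None)
    if return_clip_fraction:
        return sev, float(np.mean(total < 0))
    return sev


def simulate_network_choices(net: NetworkModel, reps_per_pair: int = 4,
                             seed: int = 0) -> ChoiceDataset:
    """Simulate choices over every ordered grid pair.

    All 100 x 100 (left, right) lottery assignments are enumerated
    ``reps_per_pair`` times each (the reference protocol uses 4, i.e.
    40,000 trials); the right option is chosen with probability
    1/(1+exp(-(SEV_R - SEV_L))).
    """
    if reps_per_pair < 1:
        raise ValueError("reps_per_pair must be at least 1")
    rng = np.random.default_rng(seed)
    gp, gm = grid_arrays()
    sev = sev_surface(net)
    left, right = np.meshgrid(np.arange(100), np.arange(100), indexing="ij")
    left = np.tile(left.ravel(), reps_per_pair)
    right = np.tile(right.ravel(), reps_per_pair)
    z = net.beta * (sev[right] - sev[left])
    p_right = 1.0 / (1.0 + np.exp(-z))
    chose_right = (rng.random(len(z)) < p_right).astype(int)
    trials = pd.DataFrame({
        "block": np.zeros(len(z), dtype=int),
        "trial": np.arange(len(z)),
        "p_left": gp[left], "m_left": gm[left],
        "p_right": gp[right], "m_right": gm[right],
        "chose_right": chose_right,
    })
    return ChoiceDataset(trials, {"generator": "simulate_network_choices",
                                  "reps_per_pair": reps_per_pair,
                                  "seed": int(seed)})


def recover_preferences(simulated: ChoiceDataset, n_starts: int = 20,
                        seed: int = 0) -> BehaviorFit:
    """Fit PT2 (with free beta) to network-simulated choices.

    beta is estimated freely even though the generator uses unit gain on
    SEV units: SEV and V live on different scales, and beta absorbs the
    scale, leaving alpha, delta and gamma scale-free.
    """
    return fit_behavior(simulated, ModelId.PT2, n_starts=n_starts, seed=seed)


@dataclass
class RecoveryResult:
    samples: pd.DataFrame             # one row per repetition: alpha, delta, gamma, beta
    means: dict[str, float]
    sds: dict[str, float]
    tests_vs_1: dict[str, float]      # empirical two-sided p-values
    tests_vs_behavior: dict[str, float] | None
    n_failed: int


def _empirical_two_sided_p(x: np.ndarray, null: float) -> float:
    lo = np.mean(x <= null)
    hi = np.mean(x >= null)
    return float(min(1.0, 2.0 * min(lo, hi)))


def repeat_recovery(net: NetworkModel, n_reps: int, seed: int = 0,
                    reps_per_pair: int = 4, n_starts: int = 10,
                    behavior_estimates: dict[str, float] | None = None
                    ) -> RecoveryResult:
    """Repeat simulate-then-refit to build parameter sampling distributions.

    Each repetition resamples only the choice noise (the cluster means
    are fixed inputs).  Parameters are tested against 1 — and, if
    supplied, against behavioral estimates — using the empirical
    distribution of the repetitions, two-sided.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(n_reps):
        sim_seed = int(rng.integers(0, 2**31 - 1))
        data = simulate_network_choices(net, reps_per_pair=reps_per_pair,
                                        seed=sim_seed)
        fit = recover_preferences(data, n_starts=n_starts,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        if not fit.converged:
            n_failed += 1
            continue
        rows.append({k: fit.params[k] for k in ("alpha", "delta", "gamma",
                                                "beta")})
    samples = pd.DataFrame(rows)
    if len(samples) == 0:
        raise RuntimeError("every recovery repetition failed to converge")
    means = {k: float(samples[k].mean()) for k in samples.columns}
    sds = {k: float(samples[k].std(ddof=1)) for k in samples.columns}
    tests_1 = {k: _empirical_two_sided_p(samples[k].to_numpy(), 1.0)
               for k in ("alpha", "delta", "gamma")}
    tests_beh = None
    if behavior_estimates is not None:
        tests_beh = {k: _empirical_two_sided_p(samples[k].to_numpy(), v)
                     for k, v in behavior_estimates.items()
                     if k in samples.columns}
    return RecoveryResult(samples, means, sds, tests_1, tests_beh, n_failed)
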