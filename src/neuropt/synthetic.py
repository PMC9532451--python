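"""Synthetic choice and single-neuron data with known ground truth.

The generators emulate the statistical structure of the cued lottery
task: a 10 x 10 grid of (probability, magnitude) cues, choice trials
pairing two uniformly drawn grid lotteries with a logistic
random-utility decision rule, and single-cue trials in which every grid
lottery is shown once per block in random order while a neuron fires
with mean rate g*w(p)*u(m) + b.  Every dataset carries the parameters
that generated it, so estimator recovery can be checked exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lotteries import grid_arrays
from .models import ModelId, choice_prob, subjective_value

logger = logging.getLogger(__name__)

#: choice-trial block length used when writing block ids (task blocks ran
#: 30-60 choice trials; the midpoint is used for bookkeeping only)
CHOICE_BLOCK_LEN = 45


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioral valuation parameters: u(m)=m**alpha, Prelec (delta, gamma), choice gain beta."""

    alpha: float = 1.0
    delta: float = 1.0
    gamma: float = 1.0
    beta: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.delta <= 0 or self.gamma <= 0:
            raise ValueError("alpha, delta and gamma must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")


@dataclass
class ChoiceDataset:
    """Binary risky-choice trials: paired lotteries plus the chosen side."""

    trials: pd.DataFrame  # columns block, trial, p_left, m_left, p_right, m_right, chose_right
    provenance: dict = field(default_factory=dict)

    REQUIRED = ("p_left", "m_left", "p_right", "m_right", "chose_right")

    def __post_init__(self) -> None:
        if len(self.trials) == 0:
            raise ValueError("a choice dataset must contain at least one trial")
        missing = [c for c in self.REQUIRED if c not in self.trials.columns]
        if missing:
            raise ValueError(f"choice table missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class NeuronSignal:
    """One neuron-epoch's trial-wise firing rates over lotteries.

    This is the unit of neural model fitting: a neuron contributes one
    signal per qualifying 1-s analysis epoch.
    """

    neuron_id: str
    region: str
    epoch_id: str
    trials: pd.DataFrame  # columns trial, p, m, rate

    def __post_init__(self) -> None:
        missing = [c for c in ("p", "m", "rate") if c not in self.trials.columns]
        if missing:
            raise ValueError(f"neural table missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Generating parameters of a synthetic neuron-epoch.

    The response follows the two-parameter-Prelec (PT2) surface
    R = g*w(p)*u(m) + b; setting alpha = delta = gamma = 1 yields the
    expected-value special case.  The coding sign is folded into g:
    g < 0 is a P-M- (negative-coding) response.
    """

    b: float
    g: float
    alpha: float = 1.0
    delta: float = 1.0
    gamma: float = 1.0
    noise_model: str = "poisson_counts"
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_model not in ("poisson_counts", "gaussian_rate"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.alpha <= 0 or self.delta <= 0 or self.gamma <= 0:
            raise ValueError("alpha, delta and gamma must be positive")

    @property
    def coding_sign(self) -> int:
        return -1 if self.g < 0 else 1

    def mean_rate(self, p, m):
        return self.g * subjective_value(ModelId.PT2, p, m, self.alpha,
                                         self.delta, self.gamma) + self.b


def simulate_choices(params: BehaviorParams, model_id: ModelId | str,
                     n_trials: int, seed: int) -> ChoiceDataset:
    """Simulate choice trials under a valuation model and logistic choice rule.

    Each trial draws the left and right lotteries independently and
    uniformly from the 100-cue grid; the right option is chosen with
    probability 1/(1+exp(-beta*(V_R - V_L))).
    """
    model_id = ModelId(model_id)
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = np.random.default_rng(seed)
    gp, gm = grid_arrays()
    v_grid = subjective_value(model_id, gp, gm, params.alpha, params.delta,
                              params.gamma)
    left = rng.integers(0, 100, size=n_trials)
    right = rng.integers(0, 100, size=n_trials)
    p_right = choice_prob(v_grid[left], v_grid[right], params.beta)
    chose_right = (rng.random(n_trials) < p_right).astype(int)
    trials = pd.DataFrame({
        "block": np.arange(n_trials) // CHOICE_BLOCK_LEN,
        "trial": np.arange(n_trials),
        "p_left": gp[left], "m_left": gm[left],
        "p_right": gp[right], "m_right": gm[right],
        "chose_right": chose_right,
    })
    prov = {"generator": "simulate_choices", "model": model_id.value,
            "params": vars(params).copy() if hasattr(params, "__dict__") else {
                "alpha": params.alpha, "delta": params.delta,
                "gamma": params.gamma, "beta": params.beta},
            "seed": int(seed)}
    return ChoiceDataset(trials, prov)


def simulate_neuron(gt: NeuronGroundTruth, trials_per_lottery: int, seed: int,
                    neuron_id: str = "sim", region: str = "DS",
                    epoch_id: str = "e1", window_s: float = 1.0) -> NeuronSignal:
    """Simulate single-cue trials for one neuron-epoch.

    Each block presents all 100 grid lotteries once in random order
    (mirroring the single-cue task); ``trials_per_lottery`` blocks are
    concatenated.  Under ``poisson_counts`` the trial rate is a Poisson
    spike count in a ``window_s`` window at rate max(0, R); under
    ``gaussian_rate`` it is R plus Gaussian noise with SD ``noise_scale``
    spikes/s.  ``noise_scale = 0`` returns the mean surface exactly.
    """
    if trials_per_lottery < 1:
        raise ValueError("trials_per_lottery must be at least 1")
    rng = np.random.default_rng(seed)
    gp, gm = grid_arrays()
    order = np.concatenate([rng.permutation(100) for _ in range(trials_per_lottery)])
    p, m = gp[order], gm[order]
    mean = np.asarray(gt.mean_rate(p, m), dtype=float)
    if gt.noise_scale == 0:
        rate = mean
    elif gt.noise_model == "poisson_counts":
        clipped = np.clip(mean, 0.0, None)
        n_trunc = int(np.sum(mean < 0))
        if n_trunc:
            logger.warning("neuron %s: %d trials with negative mean rate truncated to 0",
                           neuron_id, n_trunc)
        rate = rng.poisson(clipped * window_s) / window_s
    else:
        rate = mean + rng.normal(0.0, gt.noise_scale, size=mean.shape)
    trials = pd.DataFrame({"trial": np.arange(len(p)), "p": p, "m": m,
                           "rate": rate})
    return NeuronSignal(neuron_id, region, epoch_id, trials)


@dataclass
class SimulatedPopulation:
    """Labeled synthetic signals plus the per-signal generating parameters."""

    signals: list[NeuronSignal]
    ground_truth: pd.DataFrame  # neuron_id, label, region, b, g, alpha, delta, gamma, coding_sign


def simulate_population(cluster_spec, seed: int, trials_per_lottery: int = 1,
                        regions=("DS", "VS", "cOFC")) -> SimulatedPopulation:
    """Simulate a labeled population from cluster templates.

    ``cluster_spec`` is an iterable of ``(template, count, jitter)`` where
    ``template`` is a :class:`NeuronGroundTruth`, ``count`` the number of
    signals to draw and ``jitter`` either a scalar Gaussian SD applied to
    every parameter or a dict mapping parameter names (b, g, alpha,
    delta, gamma) to SDs.  Regions are assigned round-robin.  Labels
    (cluster index) are retained for cluster-recovery tests.
    """
    rng = np.random.default_rng(seed)
    signals: list[NeuronSignal] = []
    rows = []
    idx = 0
    for label, spec in enumerate(cluster_spec):
        template, count, jitter = spec
        if count < 1:
            raise ValueError("cluster counts must be at least 1")
        if not isinstance(jitter, dict):
            jitter = {k: float(jitter) for k in ("b", "g", "alpha", "delta", "gamma")}
        for _ in range(count):
            draw = {}
            for k in ("b", "g", "alpha", "delta", "gamma"):
                v = getattr(template, k) + rng.normal(0.0, jitter.get(k, 0.0))
                if k in ("alpha", "delta", "gamma"):
                    v = max(v, 0.05)  # keep the Prelec/utility transforms defined
                draw[k] = v
            gt = replace(template, **draw)
            region = regions[idx % len(regions)]
            nid = f"n{idx:04d}"
            sig = simulate_neuron(gt, trials_per_lottery,
                                  seed=int(rng.integers(0, 2**31 - 1)),
                                  neuron_id=nid, region=region)
            signals.append(sig)
            rows.append({"neuron_id": nid, "label": label, "region": region,
                         **draw, "coding_sign": gt.coding_sign})
            idx += 1
    return SimulatedPopulation(signals, pd.DataFrame(rows))
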