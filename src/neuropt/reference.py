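"""Published reference estimates used as simulation inputs and test anchors.

These are the PT2 behavioral estimates for the two subjects and the
mean parameters of the three largest neural clusters (C1-C3) in the
pooled DS/VS/cOFC population, as reported for the cued lottery task.
They serve as ground-truth inputs for synthetic-data studies; nothing
in the fitting code depends on them.
"""

from __future__ import annotations

from .network import ClusterParams
from .synthetic import BehaviorParams, NeuronGroundTruth

#: PT2 behavioral estimates (alpha, delta, gamma) and pooled trial counts.
#: The choice-stochasticity gain beta is not reported; the package default
#: of 10 gives realistic near-deterministic choice at large value gaps.
SUBJECTS = {
    "SUN": {"params": BehaviorParams(alpha=0.80, delta=0.57, gamma=1.43,
                                     beta=10.0),
            "n_trials": 44_883},
    "FU": {"params": BehaviorParams(alpha=0.52, delta=0.57, gamma=1.12,
                                    beta=10.0),
           "n_trials": 19_292},
}

#: Mean PT2 parameters of the three predominant clusters (C1: 48% of the
#: 272 pooled signals, concave utility + S-shaped weighting; C2: negative
#: coding; C3: convex utility), with their reported sizes.
CLUSTER_MEANS = {
    "C1": {"params": ClusterParams(b=-0.68, g=10.1, alpha=0.64, delta=1.30,
                                   gamma=2.64), "n": 130},
    "C2": {"params": ClusterParams(b=10.6, g=-10.1, alpha=0.29, delta=0.38,
                                   gamma=1.82), "n": 78},
    "C3": {"params": ClusterParams(b=2.6, g=7.2, alpha=3.2, delta=3.5,
                                   gamma=2.7), "n": 25},
}


def cluster_ground_truth(name: str, noise_model: str = "poisson_counts",
                         noise_scale: float = 1.0) -> NeuronGroundTruth:
    """A synthetic-neuron template with a reference cluster's mean parameters."""
    c = CLUSTER_MEANS[name]["params"]
    return NeuronGroundTruth(b=c.b, g=c.g, alpha=c.alpha, delta=c.delta,
                             gamma=c.gamma, noise_model=noise_model,
                             noise_scale=noise_scale)
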