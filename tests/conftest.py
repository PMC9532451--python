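import numpy as np
import pytest

from neuropt import BehaviorParams, NeuronGroundTruth, simulate_choices
from neuropt.reference import CLUSTER_MEANS, SUBJECTS


@pytest.fixture(scope="session")
def sun_params() -> BehaviorParams:
    return SUBJECTS["SUN"]["params"]


@pytest.fixture(scope="session")
def c1_truth() -> NeuronGroundTruth:
    c = CLUSTER_MEANS["C1"]["params"]
    return NeuronGroundTruth(b=c.b, g=c.g, alpha=c.alpha, delta=c.delta,
                             gamma=c.gamma)


@pytest.fixture(scope="session")
def small_pt2_choices(sun_params):
    """200 PT2 trials; small enough for exhaustive-grid likelihood checks."""
    return simulate_choices(sun_params, "PT2", 200, seed=11)
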