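import numpy as np
import pytest

from strokefc import synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def two_node_model():
    spec = synth.EffectSpec(
        condition_edges=[(1, 2, {"rest": 0.5, "L1": 0.5, "L2": 0.5})]
    )
    return synth.make_ground_truth(2, 0.5, spec, seed=0)


@pytest.fixture(scope="session")
def chain5_model():
    """5-node chain graph 1-2-3-4-5 with partial correlation 0.4 per link."""
    spec = synth.EffectSpec(
        condition_edges=[(i, i + 1, {"rest": 0.4, "L1": 0.4, "L2": 0.4}) for i in range(1, 5)]
    )
    return synth.make_ground_truth(5, 0.01, spec, seed=0, base_rho=(0.0, 0.0))


@pytest.fixture(scope="session")
def small_cohort():
    """6 patients + 8 controls, 5 nodes, short runs; no group effect."""
    spec = synth.default_effect_spec(5, n_condition_edges=3, group_delta=0.0, seed=1)
    model = synth.make_ground_truth(5, 0.2, spec, seed=1)
    return model, synth.generate_cohort(
        model, 6, 8, frames={"rest": 80, "L1": 60, "L2": 60}, seed=1
    )
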