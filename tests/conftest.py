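import numpy as np
import pytest

import motifresponse as mr


@pytest.fixture(scope="session")
def motif4():
    """Four-node motif network: triangle m-i-h plus independent edge i-j."""
    G, m, i, h, j = mr.four_node_motif()
    return G, m, i, h, j


@pytest.fixture(scope="session")
def population_reference():
    return mr.make_model("population", {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 1.1})


@pytest.fixture(scope="session")
def motif4_run(motif4, population_reference):
    """One full perturbation run on the motif network (shared, read-only)."""
    G, m, i, h, j = motif4
    steady = mr.find_steady_state(population_reference, G)
    result = mr.perturb_and_track(population_reference, G, steady, m)
    return G, steady, result


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
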