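import numpy as np
import pytest

from rulesrnn.params import (
    SimulationParams,
    scaled_down_params,
    scaled_down_training,
)
from rulesrnn.network import init_network
from rulesrnn.training import train


@pytest.fixture
def tiny_params():
    """5-unit network (4E + 1I): smallest size with the default E/I ratio."""
    return SimulationParams(n_rec=5)


@pytest.fixture
def small_params():
    """40-unit network for fast dynamical tests."""
    return SimulationParams(n_rec=40)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scaled_setup():
    p = scaled_down_params()
    t = scaled_down_training(seed=0, max_epochs=200, time_budget_s=1020.0)
    return p, t


@pytest.fixture(scope="session")
def trained_network(scaled_setup):
    """One 128E+32I network trained with SFA, shared across the slow tests.

    Training a network to criterion is the expensive step of the whole suite,
    so the emergence and perturbation tests all reuse this single realization.
    """
    p, t = scaled_setup
    w = init_network(p, np.random.default_rng(np.random.SeedSequence(t.seed)))
    res = train(w, p, t)
    return res


@pytest.fixture(scope="session")
def untrained_network(scaled_setup):
    p, t = scaled_setup
    return init_network(p, np.random.default_rng(np.random.SeedSequence(t.seed)))
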