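import logging

import numpy as np
import pytest

from omiconverge.simulate import SimulationConfig, simulate_dataset

logging.getLogger("omiconverge").setLevel(logging.ERROR)
logging.getLogger("lifelines").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort for fast unit tests (full-size runs live in acceptance)."""
    return SimulationConfig(n_network_nodes=300, min_target_neighbors=10)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_dataset(small_config, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the reference study conditions."""
    return simulate_dataset(SimulationConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
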