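import numpy as np
import pytest

from satmut import synthetic_data as sd
from satmut.core import TargetElement


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        element_length=150,
        n_tags=2000,
        n_footprints=2,
        footprint_width=10,
        rna_noise_sd=0.2,
        mutation_rate=0.01,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """(element, truth, assignment, SimulatedCounts) at a size fast enough for unit tests."""
    return sd.simulate_experiment(small_config)


@pytest.fixture
def toy_element():
    return TargetElement("toy", "ACGTACGTACGTACGTACGT")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
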