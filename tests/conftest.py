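import numpy as np
import pytest
from hypothesis import settings

from dna_accounting import SAFFRON, SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def saffron():
    return SAFFRON


@pytest.fixture
def rng():
    return np.random.default_rng(20211101)


@pytest.fixture
def quiet_cfg():
    """Simulation config with all continuous noise off (partitioning remains)."""
    return SimulationConfig(seed=7, fluorometry_cv=0.0, pipetting_cv=0.0, rain_fraction=0.0)
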