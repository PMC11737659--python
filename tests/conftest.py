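import numpy as np
import pytest

from socioclimate import DegreeDistribution, spin_up
from socioclimate.config import baseline_config
from socioclimate.synthetic_data import default_emissions


@pytest.fixture(scope="session")
def emissions():
    return default_emissions()


@pytest.fixture(scope="session")
def baseline():
    return baseline_config()


@pytest.fixture(scope="session")
def spinup(emissions, baseline):
    """2021 climate state on the synthetic ramp; shared across tests since
    the spin-up is independent of the rumor parameters."""
    return spin_up(
        emissions, baseline.climate, baseline.spinup_start, baseline.sink_in_spinup
    )


@pytest.fixture
def two_class_dd():
    return DegreeDistribution([2.0, 4.0], [0.5, 0.5])


@pytest.fixture
def single_class_dd():
    return DegreeDistribution([3.0], [1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
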