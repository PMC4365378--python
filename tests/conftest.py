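import numpy as np
import pytest
from hypothesis import settings

from gelsid.protocols import ProtocolSpec
from gelsid.workflow import (
    HAMMERSTEIN_CYCLIC_PARAMS,
    MODEL1_CYCLIC_PARAMS,
    NEOHOOKEAN_CYCLIC_PARAMS,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model1_truth():
    return dict(MODEL1_CYCLIC_PARAMS)


@pytest.fixture(scope="session")
def neohookean_truth():
    return dict(NEOHOOKEAN_CYCLIC_PARAMS)


@pytest.fixture(scope="session")
def hammerstein_truth():
    return dict(HAMMERSTEIN_CYCLIC_PARAMS)


@pytest.fixture(scope="session")
def cycles_spec():
    """The full identification protocol: 1 mm/min, 8 cycles of 15-25%."""
    return ProtocolSpec(kind="cycles", crosshead_speed=1.0, cycle_bounds=(0.15, 0.25),
                        n_cycles=8, sample_rate=10.0)


@pytest.fixture(scope="session")
def small_cycles_spec():
    """A short cyclic protocol for fast unit tests."""
    return ProtocolSpec(kind="cycles", crosshead_speed=2.0, cycle_bounds=(0.15, 0.25),
                        n_cycles=3, sample_rate=5.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
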