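import numpy as np
import pytest

from growthpeaks.model import (
    DEFAULT_GFP,
    DEFAULT_GROWTH,
    default_initial_state,
    simulate,
)


@pytest.fixture(scope="session")
def default_trajectory():
    """Default-parameter trajectory on the dt=0.01 analysis grid."""
    return simulate(DEFAULT_GROWTH, DEFAULT_GFP, default_initial_state(), dt=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210112)
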