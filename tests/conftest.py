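import numpy as np
import pytest
from hypothesis import settings

from sectorwalk.core import SimParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neutral_q2():
    return SimParams(N0=200, q=2, init_fractions=(0.5, 0.5), geometry="radial")


@pytest.fixture
def neutral_q3():
    return SimParams(N0=200, q=3, init_fractions=(1 / 3,) * 3, geometry="radial")
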