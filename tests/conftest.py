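import numpy as np
import pytest
from hypothesis import settings

from tmekin import HypoxiaParams, ParameterSet
from tmekin.params import CAPACITY_NAMES, PARAM_NAMES

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def hyp():
    return HypoxiaParams()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_params(rng):
    """Random full registry with safely positive carrying capacities."""
    def make():
        vals = {nm: rng.uniform(0.0, 2.0) for nm in PARAM_NAMES}
        for cap in CAPACITY_NAMES:
            vals[cap] = rng.uniform(0.5, 2.0)
        return ParameterSet(vals)
    return make


@pytest.fixture
def random_state(rng):
    def make():
        return rng.uniform(0.0, 1.0, 18)
    return make
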