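import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sfcoupling import gen_atlas

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def atlas8():
    return gen_atlas(8, 2)


@pytest.fixture
def atlas10():
    return gen_atlas(10, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
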