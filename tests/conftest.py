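import numpy as np
import pytest
from hypothesis import settings

from wormspan import GompertzParams, LogisticParams

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def reference():
    """Wild-type generating distribution: logistic(mu=20 d, s=2 d)."""
    return LogisticParams(20.0, 2.0)


@pytest.fixture
def gompertz_matched():
    """Gompertz parameters tuned so the median is 20 days with a slope
    comparable to the reference logistic."""
    return GompertzParams(alpha=0.0003271342, beta=0.3271342007)


@pytest.fixture
def rng():
    return np.random.default_rng(20220428)
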