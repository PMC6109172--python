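import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_mobility_warnings():
    # quenched baseline puncta legitimately trigger the indeterminate-
    # mobility warning in bulk runs
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="punctum not trackable")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
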