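import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def annulus_masks():
    """A clean annulus (outer r=10, inner r=5) and a gap-cut copy."""
    yy, xx = np.mgrid[0:32, 0:32]
    d2 = (yy - 16) ** 2 + (xx - 16) ** 2
    ring = (d2 <= 100) & (d2 > 25)
    gap = ring.copy()
    gap[(np.abs(yy - 16) <= 1) & (xx > 16)] = False  # 3-px slit through the wall
    return ring, gap
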