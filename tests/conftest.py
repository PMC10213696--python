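import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import capgrow as cg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_noiseless_exp():
    """Noiseless 6-h experiment without images: exact closed-loop input."""
    params = cg.noiseless(seed=11, duration_h=6.0)
    return cg.simulate_experiment(params, render=False)


@pytest.fixture(scope="session")
def small_rendered_exp():
    """Short paper-like run with rendered frames at 30-min cadence."""
    params = cg.paper_like(seed=21, duration_h=4.0, N0=120, um_per_px=2.0)
    return cg.simulate_experiment(params, img_stride=6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
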