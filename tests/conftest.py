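import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emahurdle as eh

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """32-participant simulated trial shared by read-only tests."""
    design = eh.StudyDesign(n_groups=4, participants_per_group=8)
    return eh.generate_dataset(design, eh.GenerativeParams(seed=7))


@pytest.fixture(scope="session")
def medium_dataset():
    """80-participant trial for model-fitting tests."""
    design = eh.StudyDesign(n_groups=8, participants_per_group=10)
    return eh.generate_dataset(design, eh.GenerativeParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
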