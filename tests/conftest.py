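import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from thermowalk import BodyModel, GradientArena, get_cohort


@pytest.fixture(scope="session")
def arena():
    return GradientArena()


@pytest.fixture(scope="session")
def body():
    return BodyModel()


@pytest.fixture(scope="session")
def wt25():
    return get_cohort("wt25")


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(12345))
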