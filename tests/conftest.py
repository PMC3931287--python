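import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lqastools import DesignSpec, nepal_survey

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def jan1999():
    return nepal_survey("jan1999")


@pytest.fixture(scope="session")
def jan2000():
    return nepal_survey("jan2000")


@pytest.fixture(scope="session")
def nepal_spec():
    return DesignSpec(p_l=0.35, p_u=0.65, alpha_max=0.10, beta_max=0.10, p_star=0.65)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
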