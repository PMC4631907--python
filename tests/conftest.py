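import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_campaign():
    """Default montane campaign with all measurement noise off."""
    from leafgx.synthetic import NoiseModel, default_paper_scenario

    return default_paper_scenario(seed=7, noise=NoiseModel(a_sd=0.0, fluorescence_cv=0.0))


@pytest.fixture(scope="session")
def default_campaign():
    from leafgx.synthetic import default_paper_scenario

    return default_paper_scenario(seed=7)
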