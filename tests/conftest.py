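import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirkit.seed_sites import MatureMiRNA, derive_site_sequences

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mir317():
    return MatureMiRNA("miR-317-3p", "UGAACACAGUGCUAAAUGAAAGA")


@pytest.fixture(scope="session")
def mir317_sites(mir317):
    return derive_site_sequences(mir317)


@pytest.fixture
def rng():
    return np.random.default_rng(20230817)
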