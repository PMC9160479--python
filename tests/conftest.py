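import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adjuscreen as ads

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-shaped cohort (73 extracts + 7 controls), seed 0."""
    return ads.generate_cohort(ads.SimConfig(seed=0))


@pytest.fixture(scope="session")
def grid():
    return ads.default_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
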