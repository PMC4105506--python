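import numpy as np
import pytest

from bsisurv import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest calibrated cohort shared by fast tests."""
    return generate_cohort(default_config(n=250, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    return generate_cohort(default_config(n=1000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
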