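import numpy as np
import pytest

from enzvec.cohort import GradientConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> GradientConfig:
    return GradientConfig()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """The study-scale cohort: 25 lakes, 44 sites."""
    return generate_cohort(default_config, seed=1)


@pytest.fixture(scope="session")
def big_cohort(default_config):
    """Scaled cohort used for calibration-recovery checks."""
    return generate_cohort(default_config, seed=1, n_sites=5000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
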