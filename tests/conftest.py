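import numpy as np
import pytest
from hypothesis import settings

from swimnet.cohort import GeneratorConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """Study-condition cohort (20 male / 18 female), fixed seed."""
    return generate_cohort(default_config, seed=11)


@pytest.fixture(scope="session")
def large_female_cohort():
    """Large two-sex cohort for Monte-Carlo parameter checks."""
    config = GeneratorConfig(n_male=1000, n_female=1000)
    return generate_cohort(config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
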