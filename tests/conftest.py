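import numpy as np
import pytest

from vitdmr import GeneratorConfig, MendelianRandomization, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_cohort=2000, n_subcohort=500)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort = generate_cohort(small_config, seed=42)
    cohort.validate()
    return cohort


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return MendelianRandomization.from_cohort(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
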