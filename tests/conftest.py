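import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from trioburden.annotation import ScoringConfig
from trioburden.simulate import (
    SimulationConfig,
    generate_frequency_table,
    generate_trio_cohort,
)


@pytest.fixture
def scoring_config():
    return ScoringConfig()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_case_families=8,
        n_control_families=40,
        n_genes=4,
        variants_per_gene=20,
        planted_fraction=0.25,
        control_planted_fraction=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    freq = generate_frequency_table(small_config)
    return generate_trio_cohort(small_config, freq)
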