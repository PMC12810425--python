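import numpy as np
import pytest

from telosim.config import SimulationConfig, load_config
from telosim.pipeline import simulate_cohort


@pytest.fixture(scope="session")
def paper_config() -> SimulationConfig:
    """The shipped calibrated configuration."""
    return load_config("paper_default")


@pytest.fixture(scope="session")
def big_cohort(paper_config):
    """One large cohort under the calibrated config (population statistics)."""
    return simulate_cohort(paper_config.replace(cohort_size=100_000), seed=101)


@pytest.fixture(scope="session")
def replicate_cohorts(paper_config):
    """200 replicate cohorts of n=140, distinct seeds."""
    return [
        simulate_cohort(paper_config, seed=1000 + i) for i in range(200)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
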