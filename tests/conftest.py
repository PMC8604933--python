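import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carrierprev import CohortSimConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (1,016 individuals, dense markers), simulated once."""
    cfg = CohortSimConfig(seed=42)
    gm, variants, truth = simulate_cohort(cfg)
    return cfg, gm, variants, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for I/O and pipeline plumbing tests."""
    cfg = CohortSimConfig(seed=7, n_individuals=40, n_markers=60)
    gm, variants, truth = simulate_cohort(cfg)
    return cfg, gm, variants, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
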