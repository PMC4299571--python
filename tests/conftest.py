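import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clustercea import published
from clustercea.effects import MCMCConfig
from clustercea.simulate import TrialDesignConfig, generate_trial

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

warnings.filterwarnings("ignore", message="ArviZ is undergoing a major refactor")


@pytest.fixture(scope="session")
def published_costs():
    return published.load_cost_summaries()


@pytest.fixture(scope="session")
def published_effects():
    return published.load_effect_summaries()


@pytest.fixture(scope="session")
def printed_totals():
    return published.printed_trial_totals()


@pytest.fixture(scope="session")
def small_trial():
    """One modest synthetic factorial trial realisation."""
    return generate_trial(TrialDesignConfig(n_clusters_per_arm=8, births_per_arm_total=40_000, seed=42))


@pytest.fixture
def short_mcmc():
    """Reduced sampler schedule for tests (the full reference run is a default, not a requirement)."""
    return MCMCConfig(n_chains=2, iterations_per_chain=2_500, burn_in=800, thin=1, seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
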