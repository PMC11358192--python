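import numpy as np
import pytest

from knowjudge import SamplerConfig, SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: fast to generate and analyse, same structure."""
    return SimulationConfig(n_informants=24, n_evaluators=10, n_categories=8,
                            trials_per_evaluator=8, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """One full-scale synthetic study (100 informants, 160 evaluators)."""
    return generate_study(SimulationConfig(seed=7))


@pytest.fixture
def fast_sampler():
    """Reduced sampler for unit tests (2 chains, light burn-in)."""
    return SamplerConfig(n_chains=2, burn_in=200, thin=5, draws_per_chain=200,
                         seed=0)
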