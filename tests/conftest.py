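import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mirsnpflow import Config, SimulationParams, simulate


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down synthetic bundle for fast unit tests."""
    return simulate(SimulationParams(
        n_variants=200, n_mirnas=40, n_genes=30, n_true_mirsnps=6,
        n_samples=150, seed=7,
    ))


@pytest.fixture(scope="session")
def default_bundle():
    """The study-scale bundle (2,000 variants, 20 planted truths)."""
    return simulate(SimulationParams(seed=11))
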