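import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpssdge import SyntheticConfig, run_pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale experiment with all contamination classes switched on."""
    return SyntheticConfig(
        n_genes=300,
        reads_per_library=40_000,
        seed=11,
        singleton_junk_fraction=0.01,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(small_config)
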