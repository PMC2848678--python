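import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_family():
    """A host plus two donors (mild / strong divergence), session-wide."""
    from hgtbench.simulator import make_species_family

    return make_species_family(2, [0.2, 0.8], seed=7)


@pytest.fixture(scope="session")
def small_host_genome(small_family):
    from hgtbench.simulator import synthesize_genome

    host, _ = small_family
    return synthesize_genome(host, 60, seed=11)
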