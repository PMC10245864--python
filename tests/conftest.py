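import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def helix50():
    from atomdiff.fixtures import build_fixture, helix_spec

    return build_fixture(helix_spec(50))


@pytest.fixture(scope="session")
def mixed_target():
    """50-residue mixed-sequence all-atom target used by the oracles."""
    from atomdiff.fixtures import build_fixture, mixed_rotamer_spec

    return build_fixture(mixed_rotamer_spec(50, seed=7))
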