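import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from solvpka.synthetic_fixtures import FixtureSpec, generate_energy_table

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_fixture():
    """Ten synthetic acids in six solvents, exact forward-model inversion."""
    return generate_energy_table(FixtureSpec(n_species=10, seed=11))


@pytest.fixture(scope="session")
def noisy_fixture():
    """Fifty acids with half-a-pKa-unit energy noise (0.0296 eV)."""
    return generate_energy_table(
        FixtureSpec(n_species=50, noise_sigma=0.0296, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
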