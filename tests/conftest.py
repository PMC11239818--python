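import numpy as np
import pytest

from deltarad.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240712)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest legal cohort for end-to-end smoke tests."""
    return CohortConfig(
        n_patients=8,
        pcr_fraction=0.5,
        grid_shape=(24, 24, 16),
        base_radius_mm=6.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    records, clinical = generate_cohort(tiny_config)
    return records, clinical
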