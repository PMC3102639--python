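import numpy as np
import pytest

from spinetorsion import (
    CohortParams,
    canonical_template,
    simulate_cohort,
    simulate_observers,
)


@pytest.fixture
def template():
    return canonical_template()


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-subject cohort at the default study parameters."""
    return simulate_cohort(CohortParams(seed=12345))


@pytest.fixture(scope="session")
def noisy_table(small_cohort):
    """Paper-scale repeated-measurement table: 25 x 3 x 2 x 2 rows."""
    return simulate_observers(small_cohort, 3, 2, noise_sigma_mm=0.4, seed=99)


@pytest.fixture(scope="session")
def noiseless_table(small_cohort):
    return simulate_observers(small_cohort, 3, 2, noise_sigma_mm=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
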