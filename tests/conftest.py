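import numpy as np
import pytest

from rmsbmr.cohort import CohortSpec, generate_cohort
from rmsbmr.organs import load_reference_profile

#: Root seed for every seeded test in the suite.
SUITE_SEED = 12345


@pytest.fixture(scope="session")
def default_cohort():
    """A default-parameter synthetic cohort large enough for recovery tests."""
    return generate_cohort(CohortSpec(n_subjects=20_000, seed=SUITE_SEED))


@pytest.fixture(scope="session")
def reference():
    """Renormalized reference male from the packaged organ table."""
    _, ref = load_reference_profile()
    return ref


@pytest.fixture(scope="session")
def organ_profile():
    """Original (70 kg) reference organ profile."""
    profile, _ = load_reference_profile()
    return profile


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
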