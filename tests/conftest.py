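import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240320)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort bundle shared by profile-level tests."""
    from mimicry_screen import CohortSpec, simulate_cohort

    return simulate_cohort(CohortSpec(n_hs=4, n_cp=6, n_viral=16), 11)
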