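import numpy as np
import pytest

import molgrad as mg


@pytest.fixture(scope="session")
def atlas60():
    return mg.make_atlas(60, seed=1)


@pytest.fixture(scope="session")
def atlas100():
    return mg.make_atlas(100, seed=2)


@pytest.fixture(scope="session")
def cohort_small(atlas60):
    """40 subjects, 60 parcels, short BOLD runs; default planted structure."""
    spec = mg.CohortSpec(n_subjects=40, n_timepoints=80, seed=7)
    return mg.simulate_cohort(spec, atlas60)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
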