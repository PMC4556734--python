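import numpy as np
import pytest

from endonet import CohortDesign, generate_cohort, generate_parcellation


@pytest.fixture(scope="session")
def small_parc():
    return generate_parcellation(20, 4, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(small_parc):
    design = CohortDesign(n_per_group=3, n_timepoints=120, seed=5)
    return generate_cohort(small_parc, design), design


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
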