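import numpy as np
import pytest

from dehydrinscan import CohortSpec, synth_cohort

# The study-sized default cohort: 32 gymnosperm trees, 185 angiosperm
# trees/shrubs, 36 angiosperm vines.
STUDY_SIZES = {
    "gymnosperm_tree": 32,
    "angiosperm_tree_shrub": 185,
    "angiosperm_vine": 36,
}


@pytest.fixture(scope="session")
def study_cohort():
    spec = CohortSpec(n_per_group=STUDY_SIZES, seed=42)
    return synth_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
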