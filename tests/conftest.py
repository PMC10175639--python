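import numpy as np
import pytest

from sonolbp import CohortConfig, cohort_feature_table, generate_cohort, split_feature_table

#: Small cohort for unit-level pipeline tests: fast, but large enough that
#: nested stratified 5-fold CV stays feasible (outer training folds keep
#: >= 5 subjects per class).
SMALL = dict(n_mild=8, n_moderate_severe=8, roi_size=(32, 32))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(seed=7, **SMALL))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return cohort_feature_table(small_cohort)


@pytest.fixture(scope="session")
def small_xy(small_table):
    return split_feature_table(small_table)


@pytest.fixture(scope="session")
def default_record():
    """One subject generated under the default study conditions (64x64 ROIs)."""
    return generate_cohort(CohortConfig(seed=11, n_mild=5, n_moderate_severe=5))[0]
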