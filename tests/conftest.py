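import numpy as np
import pytest

import tierdx


@pytest.fixture(scope="session")
def cohort():
    """The bundled 72-proband epilepsy/NDD cohort."""
    return tierdx.epilepsy_ndd_cohort()


@pytest.fixture(scope="session")
def matrix(cohort):
    return tierdx.outcome_matrix(cohort, k=3)


@pytest.fixture(scope="session")
def pathways():
    return tierdx.standard_pathways()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210948)


def random_outcome_matrix(rng, n, k):
    """Random marginal indicator matrix: each row all-zero or one-hot."""
    levels = rng.integers(0, k + 1, size=n)
    m = np.zeros((n, k), dtype=np.int64)
    diagnosed = levels > 0
    m[np.flatnonzero(diagnosed), levels[diagnosed] - 1] = 1
    return tierdx.OutcomeMatrix(m)
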