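from __future__ import annotations

import numpy as np
import pytest

from cogconnectome import make_fixture
from cogconnectome.preprocess import preprocess_pipeline


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with identical generative parameters in every cell."""
    return make_fixture("null", seed=11, n_per_group=25)


@pytest.fixture(scope="session")
def null_preprocessed(null_cohort):
    """(z-scored inverted dataset, stratification, exclusions)."""
    return preprocess_pipeline(null_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
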