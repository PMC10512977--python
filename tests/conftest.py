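import numpy as np
import pytest

from cvepauth.experiments import prepare_cohort_epochs


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three subjects, 8 trials per run — just enough structure for the
    pipeline smoke tests without meaningful simulation cost."""
    return prepare_cohort_epochs(n_subjects=3, rng_seed=11, trials_per_run=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
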