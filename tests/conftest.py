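import numpy as np
import pytest

import dmnfc
from dmnfc.bands import SLOW3, SLOW4, SLOW5


@pytest.fixture(scope="session")
def toy_config():
    """Small, fast cohort with the default implanted effect pattern."""
    return dmnfc.CohortConfig(n_group_a=6, n_group_b=6, n_volumes=120, seed=11)


@pytest.fixture(scope="session")
def toy_cohort(toy_config):
    return dmnfc.generate_cohort(toy_config)


@pytest.fixture(scope="session")
def effect_cohort():
    """Study-sized cohort with band-confined effects, shared across tests."""
    cfg = dmnfc.CohortConfig(seed=29)
    sessions, participants, truth = dmnfc.generate_cohort(cfg)
    return cfg, sessions, participants, truth


@pytest.fixture(scope="session")
def effect_cohort_matrices(effect_cohort):
    """slow-4 and slow-3 Fisher-z matrices of the effect cohort."""
    _, sessions, participants, _ = effect_cohort
    matrices, qc = dmnfc.cohort_connectivity(sessions, [SLOW4, SLOW3])
    labels = dict(zip(participants["participant_id"], participants["group"]))
    return matrices, labels, qc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
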