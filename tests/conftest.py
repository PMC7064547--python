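import numpy as np
import pytest

from gglearn.estimation import QuadratureConfig
from gglearn.prediction import CVConfig
from gglearn.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def light_cv():
    """Small CV budget used by simulation-heavy tests."""
    return CVConfig(
        n_folds=5, n_repeats=1, inner_folds=3,
        c_grid=tuple(float(c) for c in np.logspace(-2, 2, 5)), seed=0,
    )


@pytest.fixture(scope="session")
def coarse_quad():
    """Coarser posterior grid for batch experiments (accuracy ~1e-3)."""
    return QuadratureConfig(n_beta=120, n_gamma=120)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 74-patient synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(), seed=20200304)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
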