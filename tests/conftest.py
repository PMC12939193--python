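import numpy as np
import pytest

from leida import (
    CohortConfig,
    TransitionModel,
    eigenvector_series,
    simulate_cohort,
    simulate_subject,
    stack_eigenvectors,
)
from leida.synthetic import generate_state_templates


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_state_scan():
    """Noiseless scan locked into one planted state for the whole run."""
    templates = generate_state_templates(4, 90, seed=3)
    tm = TransitionModel(P=np.eye(4), pi0=np.array([1.0, 0.0, 0.0, 0.0]))
    config = CohortConfig(n_states=4, n_per_group=(1, 1), noise_sd=0.0, seed=9)
    ts, labels = simulate_subject(config, tm, templates, seed=4)
    return ts, labels, templates


@pytest.fixture(scope="session")
def small_cohort():
    """Null two-group cohort (identical transition models), test scale."""
    config = CohortConfig(n_per_group=(4, 4), n_volumes=100, seed=21)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_stack(small_cohort):
    scans, groups, _, _ = small_cohort
    series = [eigenvector_series(ts, band=None) for ts in scans]
    return stack_eigenvectors(series, groups)
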