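import numpy as np
import pytest

from connectobench.cohort import CohortSpec, TimeSeriesSession


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Tiny cohort for fast end-to-end tests."""
    return CohortSpec(
        n_subjects=4,
        n_nodes=12,
        n_timepoints=80,
        n_modules=3,
        within_strength=0.6,
        between_strength=0.1,
        subject_effect=0.3,
        session_noise=0.4,
        condition_effect=0.5,
        seed=7,
    )


def make_session(data, subject="sub001", session="rest1", condition="rest", fd=0.1):
    return TimeSeriesSession(subject, session, condition, np.asarray(data, float), fd)


@pytest.fixture
def session_factory():
    return make_session


def random_weights(rng, n, low=0.05, high=1.0):
    """Dense symmetric positive weight matrix with zero diagonal."""
    w = rng.uniform(low, high, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture
def weight_factory():
    return random_weights
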