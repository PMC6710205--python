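import numpy as np
import pytest

from dvrphys.synthetic import CohortSpec, default_true_model, generate_cohort, simulate_subject


@pytest.fixture(scope="session")
def true_model():
    return default_true_model()


@pytest.fixture(scope="session")
def clean_series(true_model):
    """Noise-free 5.5-min beat-level recording from the ground truth."""
    return simulate_subject(true_model, duration_s=330.0, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def cohort():
    """Default-size two-group cohort (16 CS, 36 MP)."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
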