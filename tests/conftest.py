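import numpy as np
import pytest
from hypothesis import settings

from neovax.binding import ToyBindingPredictor
from neovax.config import CohortConfig
from neovax.pipeline import simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def predictor() -> ToyBindingPredictor:
    return ToyBindingPredictor(4)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_patients=4, n_proteins=20, protein_length_range=(150, 300),
                        mutations_per_patient_median=10, n_clonotypes=300,
                        clonotype_depth=5000, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
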