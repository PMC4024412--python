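import numpy as np
import pytest

from pkresample import PopParams, StudyDesign, simulate_dataset


@pytest.fixture(scope="session")
def pop():
    return PopParams()


@pytest.fixture(scope="session")
def small_data(pop):
    """20-subject dataset under the default design (shared, read-only)."""
    return simulate_dataset(StudyDesign(n_subjects=20), pop, seed=101)


@pytest.fixture(scope="session")
def tiny_noise_free():
    """3 subjects, deterministic concentrations (no BSV, near-zero error)."""
    pop = PopParams(
        theta_cl=0.35, theta_v=2.0, omega_cl2=0.0, omega_v2=0.0,
        sigma_prop2=0.0, sigma_add2=1e-12,
    )
    design = StudyDesign(n_subjects=3, sample_times=(0.0, 1.0, 2.0, 4.0))
    return simulate_dataset(design, pop, seed=5), pop, design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
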