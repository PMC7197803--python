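import numpy as np
import pytest
from hypothesis import settings

from orthillusion import (
    StudyDesign,
    classify_errors,
    fit_control_reference,
    generate_cohort,
    reconstruct_reported_counts,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: The error counts reported for the two test conditions (200 ms, 33 ms).
REPORTED_COUNTS = {"test_200": 20, "test_33": 8}


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort at the default generator settings."""
    return generate_cohort(seed=20200504)


@pytest.fixture(scope="session")
def recon_cohort(design):
    """Cohort reconstructed to contain exactly the reported error counts."""
    return reconstruct_reported_counts(design, REPORTED_COUNTS, seed=101)


@pytest.fixture(scope="session")
def recon_reference(recon_cohort):
    return fit_control_reference(recon_cohort, centering_mode="pooled")


@pytest.fixture(scope="session")
def recon_labeled(recon_cohort, recon_reference):
    return classify_errors(recon_cohort, recon_reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
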