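import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort shared across read-only tests."""
    from cardioreclass.synth_cohort import CohortParams, generate_cohort

    cohort = generate_cohort(CohortParams(n_participants=6000, seed=7))
    cohort["female"] = (cohort["sex"] == "female").astype(int)
    return cohort


@pytest.fixture(scope="session")
def detection_fixtures():
    from cardioreclass.synth_cohort import generate_detection_fixtures

    return generate_detection_fixtures(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
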