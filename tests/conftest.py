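import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fibroprog import CohortDesign, ModelParameters, generate_cohort

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params() -> ModelParameters:
    """The packaged reference estimates (cohort maximum-likelihood values)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def small_cohort(ref_params):
    """A 129-patient synthetic cohort at the reference parameters."""
    records, truths = generate_cohort(CohortDesign(), ref_params, seed=20240101)
    return records, truths


@pytest.fixture
def rng():
    return np.random.default_rng(0)
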