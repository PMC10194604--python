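import hypothesis
import pytest

from mppycost import CohortParams, generate_cohort, generate_outcomes

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_params() -> CohortParams:
    return CohortParams(n_patients=40, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """A 40-patient cohort with events and outcomes, shared across tests."""
    return generate_outcomes(small_params, generate_cohort(small_params))
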