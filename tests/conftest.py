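import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from bayescbr import CbrTrialModel, TrialDesign, reference_cohort


@pytest.fixture(scope="session")
def cohort():
    """The deterministic 15-patient reference cohort."""
    return reference_cohort()


@pytest.fixture(scope="session")
def design():
    return TrialDesign()


@pytest.fixture(scope="session")
def fitted(cohort, design):
    return CbrTrialModel(cohort, design).fit()
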