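import pytest

from eyetriage.chart import reference_chart
from eyetriage.engine import reference_questionnaire
from eyetriage.simulate import fixture_study_cohort


@pytest.fixture(scope="session")
def questionnaire():
    return reference_questionnaire()


@pytest.fixture(scope="session")
def chart():
    return reference_chart()


@pytest.fixture(scope="session")
def study_cohort():
    return fixture_study_cohort()
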