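import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from illnessdeath import Cohort, CovariateProfile, SubjectRecord, reference_params

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_params():
    """Posterior-mean Weibull PH parameters of the reference cohort."""
    return reference_params()


@pytest.fixture
def small_cohort():
    """Four hand-built trajectories: refracture+death, death only,
    censored, refracture then censored."""
    records = [
        SubjectRecord(id="a", sex="woman", age=83.4, t_terminal=2.5, died=True, t_refracture=1.0),
        SubjectRecord(id="b", sex="man", age=79.0, t_terminal=2.0, died=True),
        SubjectRecord(id="c", sex="woman", age=88.3, t_terminal=3.0, died=False),
        SubjectRecord(id="d", sex="man", age=70.0, t_terminal=4.0, died=False, t_refracture=2.0),
    ]
    return Cohort.from_records(records)


def profile(sex: str, age: float) -> CovariateProfile:
    return CovariateProfile(sex, age)
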