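import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from faindex.questionnaire import (
    FREQ_5_7,
    NO,
    WALK500_YES,
    YES,
    QuestionnaireRecord,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Answers with no risk indicator and every resource indicator firing.
ALL_GOOD = dict(
    weight_loss_5kg=NO,
    changed_walk_1km=NO,
    changed_climb_10steps=NO,
    changed_car_bus=NO,
    walk_outside_freq=FREQ_5_7,
    falls_12mo=NO,
    walk_500m=WALK500_YES,
    moderate_activity_freq="1-2",
    strenuous_activity_freq="1-2",
    work_or_volunteer_7d=YES,
    fear_falling_limits=NO,
)

#: Mirror case: every risk fires, no resource fires.
ALL_BAD = dict(
    weight_loss_5kg=YES,
    changed_walk_1km=YES,
    changed_climb_10steps=YES,
    changed_car_bus=YES,
    walk_outside_freq="never",
    falls_12mo=YES,
    walk_500m="no",
    moderate_activity_freq="never",
    strenuous_activity_freq="never",
    work_or_volunteer_7d=NO,
    fear_falling_limits=YES,
)


def make_record(**overrides) -> QuestionnaireRecord:
    answers = {**ALL_GOOD, **overrides}
    return QuestionnaireRecord(**answers)


@pytest.fixture(scope="session")
def default_cohort_10k():
    """Calibrated default cohort at n=10,000 — shared across tests."""
    from faindex.simulate import SimulationConfig, generate_cohort

    cfg = SimulationConfig.defaults(seed=20140001, n=10_000)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20141219)
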