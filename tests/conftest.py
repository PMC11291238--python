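import numpy as np
import pytest
from hypothesis import settings

from nsclc_cea import SurvivalRecord, make_reference_config

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """Bundled base-case configuration (inputs, arms, parameter specs)."""
    return make_reference_config()


@pytest.fixture(scope="session")
def small_records():
    """Tiny deterministic record set: events at 1..4 months, no censoring."""
    return [SurvivalRecord(float(t), 1) for t in (1, 2, 3, 4)]


@pytest.fixture(scope="session")
def random_records():
    """200 mixed event/censoring records for estimator cross-checks."""
    rng = np.random.default_rng(42)
    times = rng.gamma(2.0, 6.0, size=200).round(2) + 0.01
    events = rng.integers(0, 2, size=200)
    if events.sum() == 0:
        events[0] = 1
    return [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]


def brute_force_km(records):
    """Independent product-limit oracle: explicit product over risk sets.

    Ties between events and censorings at the same time are events-first.
    Returns (event_times, survival_after_each_event_time).
    """
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return event_times, np.array(surv)
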