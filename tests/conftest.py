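import numpy as np
import pytest

from stressense.streams import SensorStream
from stressense.synth import (
    ParticipantProfile,
    SimConfig,
    StressorEvent,
    StressorSchedule,
    make_schedule,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def profile() -> ParticipantProfile:
    return ParticipantProfile()


@pytest.fixture(scope="session")
def schedule() -> StressorSchedule:
    return make_schedule(300.0, 6, 15.0, seed=7)


@pytest.fixture(scope="session")
def empty_schedule() -> StressorSchedule:
    return StressorSchedule([], 300.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-participant, one-trial autonomous cohort (shared, read-only)."""
    cfg = SimConfig(n_participants=3, trials=1, loops=1, seed=42,
                    session_duration=240.0, n_events=6)
    return simulate_cohort(cfg)


def make_stream(values, rate=10.0, name="x", t0=0.0):
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(values.size) / rate
    return SensorStream(name, t, values, nominal_rate=rate)


def single_event_schedule(onset=100.0, duration=6.0, intensity=1.0, total=300.0):
    return StressorSchedule([StressorEvent(onset, duration, intensity)], total)
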