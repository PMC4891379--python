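import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from timebench import (
    Event,
    EventList,
    Modality,
    Study,
    Subject,
    TimeSeriesChannel,
)
from timebench.synth import SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_channel(values, sample_rate=50.0, start_time=0.0, name="pupil"):
    return TimeSeriesChannel(
        name=name, sample_rate=sample_rate, values=np.asarray(values, float),
        start_time=start_time,
    )


@pytest.fixture
def channel_factory():
    return make_channel


@pytest.fixture
def small_cfg():
    """Small-but-complete simulation: 2 subjects x 2 trials per condition."""
    return SimulationConfig(n_subjects=2, trials_per_condition=2, seed=11)


@pytest.fixture
def toy_study():
    """One-subject study with a pupil channel containing a short gap and an
    outlier, plus two condition events."""
    values = np.full(600, 3.0)
    values[120] = 9.0  # spurious outlier
    values[300:303] = np.nan  # short gap
    ch = make_channel(values, sample_rate=50.0)
    mod = Modality(channels={"pupil": ch})
    mod.events.extend([Event("easy", 1.0), Event("difficult", 7.0)])
    study = Study(name="toy")
    study.add_subject(Subject(name="s1", substructures={"eyetracking": mod}))
    return study
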