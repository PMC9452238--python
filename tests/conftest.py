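import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caep.containers import StimulusConfig
from caep.simulate import SubjectModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def subject() -> SubjectModel:
    """One subject at the 1000 Hz normative anchors, quiet recording."""
    return SubjectModel(
        subject_id="t000",
        true_threshold_dbhl={1000: 25.0},
        p1_amplitude_80={1000: 7.36},
        p1_latency_80={1000: 225.54},
        latency_slope=1.0,
        noise_rms=5.0,
        artifact_rate=0.0,
    )


@pytest.fixture
def stimulus() -> StimulusConfig:
    return StimulusConfig(frequency_hz=1000, intensity_dbhl=80)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
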