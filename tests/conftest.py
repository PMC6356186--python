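import numpy as np
import pytest

from seatvitals import (
    NoiseSpec,
    PipelineConfig,
    SubjectProfile,
    TrueVitals,
    generate_recording,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile(
        subject_id="S_fix", age=25.0, sex="M", height=175.2, weight=75.0,
        aortic_length=0.285 * 1.752,
    )


@pytest.fixture(scope="session")
def vitals():
    return TrueVitals(sbp=120.0, dbp=80.0, sv=70.0, spo2=97.0, hr=74.3, hrv_sd=0.0)


@pytest.fixture(scope="session")
def clean_recording(subject, vitals):
    """Zero-noise 60 s recording; shared read-only across tests."""
    return generate_recording(subject, vitals, duration=60.0, fs=1000.0,
                              noise_spec=NoiseSpec.zero(), seed=1)


@pytest.fixture(scope="session")
def noisy_recording(subject, vitals):
    """Default-noise 60 s recording with RR jitter."""
    v = TrueVitals(sbp=120.0, dbp=80.0, sv=70.0, spo2=97.0, hr=74.3, hrv_sd=0.03)
    return generate_recording(subject, v, duration=60.0, fs=1000.0,
                              noise_spec=NoiseSpec(), seed=2)
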