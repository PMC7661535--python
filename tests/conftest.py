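import numpy as np
import pytest

from ppgage.beats import detect_peaks
from ppgage.io_h4h import CovariateRecord
from ppgage.preprocess import ProcessedSignal, demodulate, detrend, preprocess_recording
from ppgage.synthetic import beat_template, generate_recording, generate_truth


@pytest.fixture
def meta():
    return CovariateRecord(sex="male", age=40.0, weight=80.0, height=180.0,
                           smoking="no")


@pytest.fixture(scope="session")
def session_meta():
    return CovariateRecord(sex="female", age=35.0, weight=65.0, height=168.0,
                           smoking="no")


def make_clean_truth(seed=3, stiffness=0.5, randomness=0.5, **kw):
    m = CovariateRecord(sex="male", age=40.0, weight=80.0, height=180.0,
                        smoking="no")
    return generate_truth(f"clean{seed}", 40.0, m, stiffness=stiffness,
                          rr_randomness=randomness, seed=seed, **kw)


@pytest.fixture(scope="session")
def clean_truth():
    return make_clean_truth()


@pytest.fixture(scope="session")
def clean_recording(clean_truth):
    return generate_recording(clean_truth)


@pytest.fixture(scope="session")
def clean_signal(clean_recording):
    return preprocess_recording(clean_recording.time, clean_recording.red)


@pytest.fixture(scope="session")
def clean_peaks(clean_signal):
    return detect_peaks(clean_signal)


@pytest.fixture(scope="session")
def fixed_rr_signal():
    """Perfectly periodic 75 beats/min pulse train on a uniform 30 Hz grid."""
    sf, rr = 30.0, 0.8
    t = np.arange(0.0, 90.0, 1.0 / sf)
    template = beat_template(0.5)
    raw = ProcessedSignal(template((t % rr) / rr), sf=sf)
    return demodulate(detrend(raw))
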