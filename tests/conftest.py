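import numpy as np
import pytest

from pulseline.preprocess import preprocess
from pulseline.synth import SyntheticSpec, generate_recording


@pytest.fixture(scope="session")
def clean_ppg_recording():
    """A 60 s noiseless PPG recording at 70 BPM, target RMSSD 40 ms."""
    return generate_recording(SyntheticSpec(70, 40, duration_s=60, seed=11))


@pytest.fixture(scope="session")
def prepared_clean_ppg(clean_ppg_recording):
    return preprocess(clean_ppg_recording.signal)


@pytest.fixture(scope="session")
def ecg_recording():
    """A 60 s noiseless ECG recording with labelled R-wave times."""
    return generate_recording(
        SyntheticSpec(70, 40, duration_s=60, modality="ecg", seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
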