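import numpy as np
import pytest

from vadeeg.io import EmotionalState, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """8-channel, 4-second recording of band-limited noise at 128 Hz."""
    fs = 128.0
    data = rng.normal(0, 5, size=(8, int(4 * fs)))
    labels = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "O1", "O2"]
    return Recording(data=data, fs=fs, channel_labels=labels, subject_id="s01")


@pytest.fixture
def happy_state():
    return EmotionalState("upper", "upper", "upper")
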