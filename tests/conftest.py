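import numpy as np
import pytest

from nfkit import synth
from nfkit.core import EegRecording

FRONTAL = ("Fp1", "Fp2", "F3", "F4")


def make_tone_recording(freq_hz, amp_uv, duration_s=10.0, fs=250.0, channels=FRONTAL):
    """Pure-sinusoid recording on every channel (no noise), for filter/power oracles."""
    t = np.arange(int(duration_s * fs)) / fs
    x = amp_uv * np.sin(2 * np.pi * freq_hz * t)
    return EegRecording(
        sample_rate=fs,
        channel_labels=channels,
        samples=np.tile(x, (len(channels), 1)),
    )


def make_flat_recording(duration_s=60.0, fs=250.0, channels=FRONTAL, accel_g=1.0):
    """All-zero EEG with a constant-gravity accelerometer trace."""
    n = int(duration_s * fs)
    accel = np.zeros((3, n))
    accel[2] = accel_g
    return EegRecording(
        sample_rate=fs,
        channel_labels=channels,
        samples=np.zeros((len(channels), n)),
        accel=accel,
    )


@pytest.fixture(scope="session")
def session_recording():
    """60 s default synthetic session, shared across read-only tests."""
    return synth.generate_eeg(synth.SynthEegSpec(duration_s=60.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
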