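import numpy as np
import pytest

from planeeg import Recording
from planeeg.preprocess import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_recording(rng):
    """60 s of unit-variance white noise at 500 Hz, one channel."""
    return Recording(data=rng.standard_normal(30_000), fs=500.0,
                     group="null", source="synthetic")


def make_epochs(data, fs=500.0):
    """Wrap an (epochs, channels, samples) array as an EpochSet."""
    data = np.asarray(data, dtype=float)
    return EpochSet(data=data, fs=fs, epoch_length=data.shape[2] / fs,
                    source="synthetic")
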