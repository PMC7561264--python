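import numpy as np
import pandas as pd
import pytest

from imagentrain.spectral import StftConfig
from imagentrain.synthgen import (
    ALPHABET_SONG,
    ANALYZED_SONGS,
    GenConfig,
    RtModel,
    TrialEpochs,
    make_design,
    sample_rts,
    sensor_layout,
)


@pytest.fixture(scope="session")
def small_layout():
    return sensor_layout(12, seed=0)


@pytest.fixture(scope="session")
def small_design():
    # 3 analyzed songs, 4 trials per song per subject, 4 subjects
    return make_design(4, 2, 2, ANALYZED_SONGS, seed=7, analyzed_songs=ANALYZED_SONGS)


@pytest.fixture(scope="session")
def small_rts(small_design):
    return sample_rts(small_design, RtModel(slowdown=1.15, sd=0.5), seed=7)


@pytest.fixture(scope="session")
def quiet_gen():
    """Noiseless, evoked-free generator config on 12 channels."""
    return GenConfig(
        n_channels=12,
        n_entrained_channels=3,
        noise_amplitude=0.0,
        evoked_amplitude=0.0,
        epoch_pre=0.3,
        epoch_post=4.0,
    )


def single_channel_epochs(signal: np.ndarray, fs: float, t0: float) -> TrialEpochs:
    """Wrap a (trials, samples) or (samples,) signal as a 1-channel TrialEpochs."""
    sig = np.atleast_2d(signal)
    n_tr, n_samp = sig.shape
    times = np.arange(n_samp) / fs + t0
    return TrialEpochs(
        data=sig[:, None, :],
        times=times,
        sampling_rate=fs,
        trials=pd.DataFrame(
            {
                "subject": [0] * n_tr,
                "block": [0] * n_tr,
                "trial": range(n_tr),
                "song": [ALPHABET_SONG.name] * n_tr,
                "condition": ["listening"] * n_tr,
                "rt_seconds": [np.nan] * n_tr,
            }
        ),
        channels=pd.DataFrame({"name": ["CH000"], "x": [0.0], "y": [0.0], "z": [1.0]}),
    )


@pytest.fixture
def stft_default():
    return StftConfig()
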