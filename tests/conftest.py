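import numpy as np
import pytest

from gaitdep.io import N_JOINTS, SkeletonRecording
from gaitdep.preprocess import preprocess_recording
from gaitdep.synthetic import CohortConfig, GaitParams, synthesize_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_config():
    """A 60 s capture config — long enough for several passes at any speed."""
    return CohortConfig(duration=60.0, seed=0)


@pytest.fixture
def noiseless_params():
    return GaitParams(noise_sd=0.0, jitter_amplitude=0.0)


@pytest.fixture
def noiseless_recording(noiseless_params, short_config, rng):
    return synthesize_recording(noiseless_params, short_config, rng,
                                participant_id="noiseless")


@pytest.fixture
def noiseless_segment(noiseless_recording):
    return preprocess_recording(noiseless_recording)


@pytest.fixture
def noisy_recording(short_config, rng):
    params = GaitParams()  # default sensor noise and jitter
    return synthesize_recording(params, short_config, rng, participant_id="noisy",
                                group_label=1)


@pytest.fixture
def static_recording():
    """A static standing pose, translated nowhere: T=200 frames."""
    positions = np.zeros((200, N_JOINTS, 3))
    positions[:, :, 1] = np.linspace(0, 1, N_JOINTS)[None, :]
    return SkeletonRecording(positions=positions, frame_rate=30.0,
                             participant_id="static")
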