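import numpy as np
import pytest

from nasrec.synthvid import SynthSpec, VideoVolume, generate_clip


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def bar_clip():
    """A clean translating-bar clip reused across detector/patch tests."""
    video, label = generate_clip(
        SynthSpec("translating_bar", subject_seed=3, clip_seed=5, snr_db=np.inf)
    )
    return video


@pytest.fixture()
def static_video(rng):
    """Temporally constant video with spatial texture."""
    frame = rng.random((40, 40))
    return VideoVolume(np.repeat(frame[None], 40, axis=0))


def oscillating_blob(shape=(40, 40, 40), center=(20, 20), amp=1.0, freq=4 / 3.0,
                     sigma=3.0, base=0.5):
    """Gaussian blob whose intensity oscillates sinusoidally at ``freq``."""
    T, H, W = shape
    y, x = np.mgrid[0:H, 0:W]
    blob = np.exp(-((y - center[0]) ** 2 + (x - center[1]) ** 2) / (2 * sigma**2))
    t = np.arange(T)
    mod = 0.5 * amp * np.sin(2 * np.pi * freq * t)
    frames = base + mod[:, None, None] * blob[None]
    return VideoVolume(np.clip(frames, 0.0, 1.0))
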