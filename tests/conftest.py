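import numpy as np
import pytest

from chirpnet import frontend as fe
from chirpnet import synthetic_audio as sa


@pytest.fixture(scope="session")
def mel_32k() -> fe.MelParams:
    return fe.MelParams(sample_rate=32_000.0)


@pytest.fixture(scope="session")
def single_pulse_clip() -> sa.AudioClip:
    """Noise-free 7-s clip with one 6.5 kHz pulse starting at 2 s."""
    return sa.make_pulse_clip(
        [sa.PulseSpec(center_freq=6_500.0, bandwidth=400.0, onset=2.0,
                      duration=1.0)],
        clip_len=7.0, sample_rate=32_000.0, noise_rms=0.0, seed=17)


@pytest.fixture(scope="session")
def small_mel_16k() -> fe.MelParams:
    """Compact spectrogram geometry used by the desk-scale training runs."""
    return fe.MelParams(sample_rate=16_000.0, n_mels=64, n_fft=1024,
                        hop_length=512)


def stacks_for(dataset: sa.SyntheticDataset, mel: fe.MelParams,
               spec: fe.SlideSpec | None = None) -> np.ndarray:
    spec = spec or fe.SlideSpec()
    return np.stack([fe.build_slide_stack(c, spec, mel).slices
                     for c in dataset.clips]).astype(np.float32)


@pytest.fixture(scope="session")
def tiny_trainset(small_mel_16k):
    """3 classes x 10 clips of 1.5 s at 16 kHz -> (30, 4, 64, 16) stacks."""
    ds = sa.make_dataset(3, 10, clip_len=1.5, sample_rate=16_000.0, seed=3)
    X = stacks_for(ds, small_mel_16k)
    y = np.array(ds.labels)
    return X, y
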