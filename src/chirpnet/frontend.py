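"""Audio-to-model-input transforms.

Two representations are produced from a standardized clip (mono, fixed rate,
fixed length):

* the *stand-alone* path: one whole-clip mel spectrogram resized to a
  3x224x224 image, consumed by ImageNet-style classifiers;
* the *hybrid* path: a sliding window of length ``Ws`` ms and hop ``Hs`` ms is
  run over the raw audio, each window is converted to a mel spectrogram, and
  the ordered stack of per-window slices (the ``SlideStack``) is the model
  input.  With the default geometry (7 s at 32 kHz, Ws=500, Hs=250, 128 mel
  bands, FFT 2048, hop 512) a clip yields 26 slices of shape 128x32.

Slide-count convention: ``n = floor((T_ms - Ws) / Hs)`` — the final
partially-usable start offset is dropped.  This is the unique simple
convention that yields 26 slides for a 7-s clip at (500, 250) ms; the naive
``floor((T-Ws)/Hs) + 1`` would give 27.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly
from skimage.transform import resize as _sk_resize

from .synthetic_audio import AudioClip, ValidationError


class ClipTooShortError(ValueError):
    """Clip rejected: shorter than the requested standard length."""

    def __init__(self, clip_id, have: float, need: float):
        self.clip_id = clip_id
        super().__init__(
            f"clip {clip_id!r} is {have:.3f} s, shorter than the required "
            f"{need:.3f} s; it is ignored"
        )


@dataclass(frozen=True)
class SlideSpec:
    """Sliding-window geometry: window length Ws and hop Hs, in milliseconds."""

    window_ms: float = 500.0
    hop_ms: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.hop_ms <= self.window_ms):
            raise ValidationError("require 0 < hop_ms <= window_ms")

    def n_slides(self, clip_ms: float) -> int:
        return int(np.floor((clip_ms - self.window_ms) / self.hop_ms))


@dataclass(frozen=True)
class MelParams:
    """Mel-spectrogram settings (defaults follow the study geometry)."""

    sample_rate: float = 32_000.0
    n_mels: int = 128
    n_fft: int = 2048
    hop_length: int = 512
    fmin: float = 0.0
    fmax: float | None = None  # None -> Nyquist

    def __post_init__(self) -> None:
        if self.n_fft < self.hop_length:
            raise ValidationError("n_fft must be >= hop_length")
        if self.n_mels < 1:
            raise ValidationError("n_mels must be >= 1")


@dataclass
class SlideStack:
    """Ordered per-slide mel spectrograms: (n_slides, n_mels, n_frames).

    Slide k covers ``[k*Hs, k*Hs + Ws)`` milliseconds of the clip (0-based),
    which is also the time axis used when memory traces are aligned with the
    spectrogram.
    """

    slices: np.ndarray
    clip_id: object
    spec: SlideSpec
    mel: MelParams

    def __post_init__(self) -> None:
        if self.slices.ndim != 3:
            raise ValidationError("slices must be (n_slides, n_mels, n_frames)")
        if not np.all(np.isfinite(self.slices)):
            raise ValidationError("slices contain non-finite values")

    @property
    def n_slides(self) -> int:
        return self.slices.shape[0]

    def slide_times(self) -> np.ndarray:
        """Start time of each slide in seconds (k * Hs)."""
        return np.arange(self.n_slides) * self.spec.hop_ms / 1000.0


@dataclass
class ClipImage:
    """Whole-clip spectrogram as a 3x224x224 image (3 identical channels)."""

    pixels: np.ndarray
    clip_id: object

    def __post_init__(self) -> None:
        if self.pixels.shape != (3, 224, 224):
            raise ValidationError("ClipImage must be exactly 3x224x224")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixels contain non-finite values")


# ---------------------------------------------------------------------------
# standardization


def standardize_clip(clip: AudioClip, target_rate: float = 32_000.0,
                     target_len: float = 7.0) -> AudioClip:
    """Mono mixdown, resample to ``target_rate``, keep the first
    ``target_len`` seconds.  Shorter clips are rejected (the corpus curation
    rule: recordings shorter than the standard length are ignored)."""
    x = np.asarray(clip.samples, dtype=np.float64)
    if x.ndim == 2:
        # accept either (channels, samples) or (samples, channels)
        axis = 0 if x.shape[0] <= x.shape[1] else 1
        x = x.mean(axis=axis)
    if clip.duration + 1e-9 < target_len:
        raise ClipTooShortError(clip.clip_id, clip.duration, target_len)
    if clip.sample_rate != target_rate:
        from fractions import Fraction

        frac = Fraction(int(round(target_rate)), int(round(clip.sample_rate)))
        x = resample_poly(x, frac.numerator, frac.denominator)
    n = int(round(target_len * target_rate))
    if x.size < n:  # rounding slack from the resampler
        x = np.pad(x, (0, n - x.size))
    out = AudioClip(samples=x[:n], sample_rate=target_rate, label=clip.label,
                    clip_id=clip.clip_id)
    return out


def slice_clip(clip: AudioClip, spec: SlideSpec) -> list[AudioClip]:
    """Cut the clip into ``floor((T-Ws)/Hs)`` windows; window k starts at
    ``k*Hs`` ms and has exact length ``Ws`` ms."""
    clip_ms = clip.duration * 1000.0
    if clip_ms < spec.window_ms + spec.hop_ms:
        raise ValidationError(
            f"clip of {clip_ms:.0f} ms too short for one "
            f"({spec.window_ms:.0f}, {spec.hop_ms:.0f}) ms window"
        )
    n = spec.n_slides(clip_ms)
    win = int(round(spec.window_ms / 1000.0 * clip.sample_rate))
    out = []
    for k in range(n):
        start = int(round(k * spec.hop_ms / 1000.0 * clip.sample_rate))
        out.append(
            AudioClip(samples=clip.samples[start : start + win],
                      sample_rate=clip.sample_rate, label=clip.label,
                      clip_id=clip.clip_id)
        )
    return out


# ---------------------------------------------------------------------------
# mel spectrogram (hand-rolled: filter bank on HTK mel scale + centred STFT)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_center_frequencies(mel: MelParams) -> np.ndarray:
    """Centre frequency (Hz) of each triangular mel filter."""
    fmax = mel.fmax if mel.fmax is not None else mel.sample_rate / 2
    edges = mel_to_hz(
        np.linspace(hz_to_mel(mel.fmin), hz_to_mel(fmax), mel.n_mels + 2)
    )
    return edges[1:-1]


def mel_filterbank(mel: MelParams) -> np.ndarray:
    """Triangular filter bank, shape (n_mels, n_fft//2 + 1)."""
    fmax = mel.fmax if mel.fmax is not None else mel.sample_rate / 2
    n_bins = mel.n_fft // 2 + 1
    fft_freqs = np.linspace(0, mel.sample_rate / 2, n_bins)
    edges = mel_to_hz(
        np.linspace(hz_to_mel(mel.fmin), hz_to_mel(fmax), mel.n_mels + 2)
    )
    fb = np.zeros((mel.n_mels, n_bins))
    for i in range(mel.n_mels):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


DB_FLOOR = -80.0


def power_to_db(power: np.ndarray, floor_db: float = DB_FLOOR) -> np.ndarray:
    """dB relative to the array's max power, floored at ``floor_db``."""
    ref = power.max()
    if ref <= 0:
        return np.full_like(power, floor_db)
    db = 10.0 * np.log10(np.maximum(power, 1e-300) / ref)
    return np.maximum(db, floor_db)


def melspectrogram(window: AudioClip | np.ndarray, mel: MelParams,
                   log_scale: bool = True) -> np.ndarray:
    """Power mel spectrogram of one window, shape (n_mels, n_frames) with
    ``n_frames = 1 + floor(len/hop)`` (centred framing, Hann window,
    reflect padding)."""
    x = window.samples if isinstance(window, AudioClip) else np.asarray(window)
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("empty window")
    pad = mel.n_fft // 2
    if x.size >= pad + 1:
        xp = np.pad(x, pad, mode="reflect")
    else:
        xp = np.pad(x, pad, mode="constant")
    n_frames = 1 + x.size // mel.hop_length
    frames = np.lib.stride_tricks.sliding_window_view(xp, mel.n_fft)[
        :: mel.hop_length
    ][:n_frames]
    win = np.hanning(mel.n_fft)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2  # (frames, bins)
    melspec = mel_filterbank(mel) @ spec.T  # (n_mels, n_frames)
    if log_scale:
        melspec = power_to_db(melspec)
    return melspec


# ---------------------------------------------------------------------------
# model inputs


def clip_image(clip: AudioClip, mel: MelParams | None = None) -> ClipImage:
    """Whole-clip mel spectrogram, bilinearly resized to 224x224, replicated
    to 3 identical channels (no colormap)."""
    mel = mel or MelParams(sample_rate=clip.sample_rate)
    m = melspectrogram(clip, mel, log_scale=True)
    img = _sk_resize(m, (224, 224), order=1, preserve_range=True,
                     anti_aliasing=False)
    return ClipImage(pixels=np.repeat(img[None], 3, axis=0), clip_id=clip.clip_id)


def build_slide_stack(clip: AudioClip, spec: SlideSpec | None = None,
                      mel: MelParams | None = None,
                      log_scale: bool = True) -> SlideStack:
    """Compose :func:`slice_clip` and :func:`melspectrogram` into the hybrid
    models' input stack."""
    spec = spec or SlideSpec()
    mel = mel or MelParams(sample_rate=clip.sample_rate)
    windows = slice_clip(clip, spec)
    slices = np.stack([melspectrogram(w, mel, log_scale=log_scale)
                       for w in windows])
    return SlideStack(slices=slices, clip_id=clip.clip_id, spec=spec, mel=mel)


# ---------------------------------------------------------------------------
# caching (one compressed array file per clip, keyed by clip id + settings)


def settings_hash(spec: SlideSpec, mel: MelParams) -> str:
    key = repr((spec, mel)).encode()
    return hashlib.sha1(key).hexdigest()[:12]


def cache_stack(stack: SlideStack, cache_dir: str | Path) -> Path:
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / (
        f"{stack.clip_id}_{settings_hash(stack.spec, stack.mel)}.npz"
    )
    np.savez_compressed(path, slices=stack.slices)
    return path


def load_cached_stack(clip_id, spec: SlideSpec, mel: MelParams,
                      cache_dir: str | Path) -> SlideStack | None:
    path = Path(cache_dir) / f"{clip_id}_{settings_hash(spec, mel)}.npz"
    if not path.exists():
        return None
    with np.load(path) as z:
        return SlideStack(slices=z["slices"], clip_id=clip_id, spec=spec,
                          mel=mel)
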