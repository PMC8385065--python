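"""Seeded synthetic bird-call audio.

Real bird recordings carry class identity in band-limited tonal pulses —
short tone bursts at a species-typical centre frequency, repeated in a
species-typical rhythm, over a broadband noise floor.  This module generates
clips with exactly that structure so the whole classification pipeline is
testable without any audio downloads: each class is assigned a centre
frequency and a pulse count, and per-clip jitter (onset, duration, amplitude)
comes from a hierarchical seeded stream so that adding clips never perturbs
earlier ones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import tukey


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class AudioClip:
    """Mono audio: dimensionless samples in [-1, 1] at ``sample_rate`` Hz."""

    samples: np.ndarray
    sample_rate: float
    label: object | None = None
    clip_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 2:  # channels x samples or samples x channels
            pass  # multi-channel allowed; frontend mixes down
        elif self.samples.ndim != 1:
            raise ValidationError("samples must be 1-D (or 2-D multichannel)")
        if self.samples.size < 1:
            raise ValidationError("clip must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        n = self.samples.shape[-1]
        return n / self.sample_rate


@dataclass
class PulseSpec:
    """One windowed tone burst: centre frequency/bandwidth in Hz, onset and
    duration in seconds, dimensionless amplitude."""

    center_freq: float
    bandwidth: float
    onset: float
    duration: float
    amplitude: float = 0.5

    def validate(self, clip_len: float, sample_rate: float) -> None:
        if self.onset < 0:
            raise ValidationError("pulse onset must be >= 0")
        if self.onset + self.duration > clip_len + 1e-12:
            raise ValidationError(
                f"pulse [{self.onset}, {self.onset + self.duration}] s exceeds "
                f"clip bounds (clip_len={clip_len} s)"
            )
        if not (0 < self.center_freq < sample_rate / 2):
            raise ValidationError(
                f"center_freq {self.center_freq} Hz outside (0, Nyquist="
                f"{sample_rate / 2} Hz)"
            )


@dataclass
class SyntheticDataset:
    clips: list[AudioClip]
    labels: list[int]
    seed: int
    class_defs: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.clips) != len(self.labels):
            raise ValidationError("labels must align 1:1 with clips")

    def __len__(self) -> int:
        return len(self.clips)


# ---------------------------------------------------------------------------
# clip synthesis

#: Tukey taper fraction for pulse envelopes.  A raised-cosine edge keeps the
#: burst's energy inside its declared band (no rectangular-edge splatter).
PULSE_TAPER = 0.5


def make_pulse_clip(
    pulses: Sequence[PulseSpec],
    clip_len: float,
    sample_rate: float = 32_000.0,
    noise_rms: float = 0.0,
    seed: int = 0,
) -> AudioClip:
    """Synthesize one clip: Tukey-windowed tone bursts over white noise.

    Each pulse contributes ``amplitude * tukey(t) * sin(2*pi*f(t)*t)`` where
    the instantaneous frequency wanders slowly inside
    ``center_freq +- bandwidth/2``.  Outside all pulses only the
    ``noise_rms``-level Gaussian floor remains; the result is clipped to
    [-1, 1].
    """
    if clip_len <= 0:
        raise ValidationError("clip_len must be positive")
    n = int(round(clip_len * sample_rate))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    if noise_rms > 0:
        x += rng.normal(0.0, noise_rms, size=n)
    for p in pulses:
        p.validate(clip_len, sample_rate)
        i0 = int(round(p.onset * sample_rate))
        m = int(round(p.duration * sample_rate))
        m = min(m, n - i0)
        if m <= 0:
            continue
        t = np.arange(m) / sample_rate
        # slow sinusoidal FM keeps energy within center_freq +- bandwidth/2
        fm_rate = 2.0 / max(p.duration, 1e-9)
        inst_freq = p.center_freq + 0.5 * p.bandwidth * np.sin(
            2 * np.pi * fm_rate * t + rng.uniform(0, 2 * np.pi)
        ) * (p.bandwidth > 0)
        phase = 2 * np.pi * np.cumsum(inst_freq) / sample_rate
        env = tukey(m, PULSE_TAPER)
        x[i0 : i0 + m] += p.amplitude * env * np.sin(phase)
    np.clip(x, -1.0, 1.0, out=x)
    return AudioClip(samples=x, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# dataset generation

#: Class encoding: class i calls at DEFAULT_F0 + i*DEFAULT_DF Hz with
#: 1 + (i mod 3) pulses per clip.  Deterministic, monotone class separation.
DEFAULT_F0 = 2_000.0
DEFAULT_DF = 1_200.0
DEFAULT_BANDWIDTH = 400.0
DEFAULT_NOISE_RMS = 0.01


def class_pulse_params(class_index: int, f0: float = DEFAULT_F0,
                       df: float = DEFAULT_DF) -> dict:
    """Deterministic per-class call parameters."""
    return {
        "center_freq": f0 + class_index * df,
        "n_pulses": 1 + class_index % 3,
        "bandwidth": DEFAULT_BANDWIDTH,
    }


def make_dataset(
    n_classes: int,
    per_class: int,
    clip_len: float = 7.0,
    sample_rate: float = 32_000.0,
    seed: int = 0,
    noise_rms: float = DEFAULT_NOISE_RMS,
    f0: float = DEFAULT_F0,
    df: float = DEFAULT_DF,
) -> SyntheticDataset:
    """Generate a labelled, shuffled synthetic dataset.

    Classes differ deterministically (centre frequency and pulse count);
    within-class onset/duration/amplitude jitter is drawn from a per-clip
    substream spawned from the single global seed, so clip k's samples do not
    depend on how many clips are generated.
    """
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    if per_class < 1:
        raise ValidationError("per_class must be >= 1")
    top = f0 + (n_classes - 1) * df + DEFAULT_BANDWIDTH
    if top >= sample_rate / 2:
        raise ValidationError(
            f"class frequencies reach {top} Hz >= Nyquist; lower n_classes, "
            f"f0 or df, or raise sample_rate"
        )
    clips: list[AudioClip] = []
    labels: list[int] = []
    class_defs = {c: class_pulse_params(c, f0, df) for c in range(n_classes)}
    for c in range(n_classes):
        params = class_defs[c]
        for j in range(per_class):
            # per-clip substream keyed by (class, within-class index):
            # adding classes or clips never perturbs earlier clips
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(c, j))
            )
            n_p = params["n_pulses"]
            # rhythm: pulses evenly spread with jitter, fit inside the clip
            max_dur = clip_len / (2 * n_p)
            pulses = []
            for k in range(n_p):
                dur = rng.uniform(0.6, 1.0) * max_dur
                slot = clip_len / n_p
                onset = k * slot + rng.uniform(0.05, 0.95) * (slot - dur)
                pulses.append(
                    PulseSpec(
                        center_freq=params["center_freq"],
                        bandwidth=params["bandwidth"],
                        onset=onset,
                        duration=dur,
                        amplitude=rng.uniform(0.35, 0.6),
                    )
                )
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clip = make_pulse_clip(pulses, clip_len, sample_rate,
                                   noise_rms=noise_rms, seed=clip_seed)
            clip.label = c
            clip.clip_id = f"synth_c{c:02d}_{j:04d}"
            clips.append(clip)
            labels.append(c)
    # label-aligned linear shuffle
    perm = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(2**20,))
    ).permutation(len(clips))
    clips = [clips[i] for i in perm]
    labels = [labels[i] for i in perm]
    return SyntheticDataset(clips=clips, labels=labels, seed=seed,
                            class_defs=class_defs)


# ---------------------------------------------------------------------------
# memory probes (per-timestep scalar drives for the memory analyses)


def make_memory_probe(
    kind: Literal["single_pulse", "double_pulse"],
    n_steps: int,
    onset: int | None = None,
    width: int | None = None,
    smooth: bool = True,
) -> np.ndarray:
    """Per-timestep scalar drive: zero until ``onset``, then one (or two
    disjoint) pulses.

    ``smooth=True`` uses a raised-cosine (Hann) envelope whose samples are
    all strictly positive inside the pulse; ``smooth=False`` gives a
    rectangular pulse.  Defaults: onset at n/8, width n/3 (single) or n/5
    (double), echoing the pulse geometry of the memory-trace figures.
    """
    if kind not in ("single_pulse", "double_pulse"):
        raise ValidationError(f"unknown probe kind {kind!r}")
    if n_steps < 4:
        raise ValidationError("n_steps must be >= 4")
    if onset is None:
        onset = max(1, n_steps // 8)
    if width is None:
        width = max(1, n_steps // (3 if kind == "single_pulse" else 5))
    x = np.zeros(n_steps)

    def envelope(w: int) -> np.ndarray:
        if not smooth:
            return np.ones(w)
        return np.hanning(w + 2)[1:-1]  # strictly positive inside

    def add(o: int, w: int) -> None:
        w = min(w, n_steps - o)
        if w <= 0:
            raise ValidationError("pulse does not fit inside n_steps")
        x[o : o + w] += envelope(w)

    add(onset, width)
    if kind == "double_pulse":
        gap = max(1, width // 2)
        add(onset + width + gap, width)
    return x


# ---------------------------------------------------------------------------
# on-disk export


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path,
                  dtype: str = "float32") -> Path:
    """Write clips as WAV plus a CSV manifest (path,label,duration_s,sample_rate)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "duration_s", "sample_rate"])
        for clip, label in zip(dataset.clips, dataset.labels):
            name = f"{clip.clip_id or id(clip)}.wav"
            path = out / name
            sr = int(round(clip.sample_rate))
            if dtype == "float32":
                wavfile.write(path, sr, clip.samples.astype(np.float32))
            elif dtype == "int16":
                wavfile.write(
                    path, sr, np.round(clip.samples * 32767).astype(np.int16)
                )
            else:
                raise ValidationError("dtype must be float32 or int16")
            writer.writerow([name, label, f"{clip.duration:.6f}", sr])
    return manifest


def read_manifest(manifest: str | Path) -> tuple[list[AudioClip], list[int]]:
    """Load clips listed in a manifest CSV (paths relative to the manifest)."""
    manifest = Path(manifest)
    clips: list[AudioClip] = []
    labels: list[int] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            sr, data = wavfile.read(manifest.parent / row["path"])
            if data.dtype.kind == "i":
                data = data / float(np.iinfo(data.dtype).max)
            clip = AudioClip(samples=np.asarray(data, dtype=np.float64).T,
                             sample_rate=float(sr),
                             clip_id=Path(row["path"]).stem)
            clip.label = row["label"]
            clips.append(clip)
            labels.append(row["label"])
    return clips, labels
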