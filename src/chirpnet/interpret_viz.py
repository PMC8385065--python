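"""Interpretation instruments.

Three analyses probe what the trained models learned:

* **memory traces** — the LMU memory state ``m_t`` recorded at every slide
  step of a forward pass, rendered as a heat-map time-aligned with the
  spectrogram (slide k sits at ``k * Hs`` seconds).  Channels stay exactly
  zero until the first nonzero drive arrives: no signal history, no
  projection.
* **softmax signatures** — each model's softmax outputs over a fixed test
  set, concatenated into one long vector and compared across models by PCA,
  with two anchors: *True* (concatenated one-hot labels) and *Random*
  (uniform 1/n_classes everywhere, the maximum-entropy output).
* **embeddings** — penultimate-layer activations of test samples for the
  most frequent species, projected to 2-D with a seeded t-SNE.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from ._nn import LMULayer
from .frontend import SlideStack
from .model_zoo import HybridModel
from .synthetic_audio import ValidationError


@dataclass
class MemoryTrace:
    """Memory-channel values (d x n_steps) with the slide-time axis."""

    values: np.ndarray
    slide_times: np.ndarray
    clip_id: object = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.slide_times.size:
            raise ValidationError("one trace column per slide step")


@dataclass
class ModelSignature:
    """Concatenated softmax outputs over a fixed test set."""

    vector: np.ndarray
    model_id: str
    n_classes: int

    def blocks(self) -> np.ndarray:
        return self.vector.reshape(-1, self.n_classes)


@dataclass
class EmbeddingSet:
    points: np.ndarray  # (n_samples, 2)
    labels: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if self.points.shape[0] != np.asarray(self.labels).size:
            raise ValidationError("one point per embedded sample")


# ---------------------------------------------------------------------------
# memory traces


def memory_trace(model: HybridModel, stack: SlideStack | np.ndarray
                 ) -> MemoryTrace:
    """Run one clip forward and record the (top) LMU layer's memory state at
    every slide step."""
    lmus = model.lmu_layers()
    if not lmus:
        raise ValidationError("model has no LMU temporal layer")
    if isinstance(stack, SlideStack):
        slices = stack.slices
        times = stack.slide_times()
        clip_id = stack.clip_id
    else:
        slices = np.asarray(stack)
        times = np.arange(slices.shape[0]) * 0.25
        clip_id = None
    model.forward(slices[None], train=False)
    top_lmu: LMULayer = lmus[-1]  # top layer: closest to the output
    return MemoryTrace(values=top_lmu.last_memory_trace(0),
                       slide_times=times, clip_id=clip_id)


# ---------------------------------------------------------------------------
# softmax signatures and the model-comparison plane


def signature(model, X: np.ndarray, model_id: str = "model",
              batch_size: int = 32) -> ModelSignature:
    """Concatenate the model's softmax outputs over the test set, in sample
    order (order must be identical across compared models)."""
    probs = []
    for i in range(0, len(X), batch_size):
        probs.append(model.forward(X[i:i + batch_size], train=False))
    P = np.concatenate(probs, axis=0)
    return ModelSignature(vector=P.reshape(-1), model_id=model_id,
                          n_classes=P.shape[1])


def reference_signatures(labels, n_classes: int
                         ) -> tuple[ModelSignature, ModelSignature]:
    """The two anchors: True = concatenated one-hot labels; Random = uniform
    probability (maximum entropy) for every sample."""
    y = np.asarray(labels)
    onehot = np.zeros((y.size, n_classes))
    onehot[np.arange(y.size), y] = 1.0
    uniform = np.full((y.size, n_classes), 1.0 / n_classes)
    return (ModelSignature(onehot.reshape(-1), "True", n_classes),
            ModelSignature(uniform.reshape(-1), "Random", n_classes))


def pca_compare(signatures: list[ModelSignature]) -> dict[str, np.ndarray]:
    """Centre the signature matrix and project every model onto the two
    directions of maximum variance.  Returns {model_id: (2,) coords}."""
    if len(signatures) < 3:
        raise ValidationError("need at least 3 signatures for a PCA plane")
    lengths = {s.vector.size for s in signatures}
    if len(lengths) != 1:
        raise ValidationError("signatures must share the test set "
                              "(unequal lengths)")
    M = np.stack([s.vector for s in signatures])
    coords = PCA(n_components=2).fit_transform(M)
    return {s.model_id: coords[i] for i, s in enumerate(signatures)}


# ---------------------------------------------------------------------------
# representation embeddings


def penultimate_activations(model, X: np.ndarray, batch_size: int = 32
                            ) -> np.ndarray:
    """Input to the final output layer, one row per sample."""
    acts = []
    for i in range(0, len(X), batch_size):
        model.forward(X[i:i + batch_size], train=False)
        acts.append(model.last_penultimate.copy())
    return np.concatenate(acts, axis=0)


def embed_representations(model, X: np.ndarray, labels, top_k_species: int,
                          method: str = "tsne", seed: int = 0,
                          perplexity: float = 30.0) -> EmbeddingSet:
    """t-SNE the penultimate-layer vectors of the ``top_k_species`` most
    frequent classes (seeded, hence reproducible)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if top_k_species > classes.size:
        raise ValidationError(
            f"top_k_species={top_k_species} exceeds the {classes.size} "
            f"species present")
    keep = classes[np.argsort(counts)[::-1][:top_k_species]]
    mask = np.isin(y, keep)
    feats = penultimate_activations(model, X[mask])
    if method != "tsne":
        raise ValidationError(f"unknown embedding method {method!r}")
    perp = min(perplexity, max(2.0, (mask.sum() - 1) / 3))
    pts = TSNE(n_components=2, random_state=seed, perplexity=perp,
               init="pca").fit_transform(feats)
    return EmbeddingSet(points=pts, labels=y[mask], method=method)


# ---------------------------------------------------------------------------
# rendering (fixed style, no timestamps: identical inputs -> identical bytes)


def _save(fig, out_path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=100, metadata={"Software": None,
                                             "CreationDate": None})
    plt.close(fig)
    return out_path


def render_trace(trace: MemoryTrace, out_path,
                 spectrogram: np.ndarray | None = None) -> Path:
    """Spectrogram (top) time-aligned with the signed memory heat-map
    (bottom); symmetric colour scale because Legendre coefficients are
    signed."""
    n_rows = 2 if spectrogram is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(8, 5), sharex=False)
    axes = np.atleast_1d(axes)
    empty = trace.slide_times.size == 0
    t0 = 0.0 if empty else float(trace.slide_times[0])
    t1 = (t0 + 1.0 if trace.slide_times.size < 2
          else float(trace.slide_times[-1]))
    if spectrogram is not None:
        axes[0].imshow(spectrogram, origin="lower", aspect="auto",
                       extent=(t0, t1, 0, spectrogram.shape[0]))
        axes[0].set_ylabel("mel bin")
    if not empty:
        vmax = float(np.abs(trace.values).max()) or 1.0
        axes[-1].imshow(trace.values, origin="lower", aspect="auto",
                        cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                        extent=(t0, t1, 0, trace.values.shape[0]))
    axes[-1].set_xlabel("time (s)")
    axes[-1].set_ylabel("memory channel")
    return _save(fig, out_path)


def render_signature_plane(coords: dict[str, np.ndarray], out_path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    for name, (x, y) in coords.items():
        marker = "*" if name in ("True", "Random") else "o"
        ax.scatter([x], [y], marker=marker, s=80)
        ax.annotate(name, (x, y), fontsize=8)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    return _save(fig, out_path)


def render_embedding(emb: EmbeddingSet, out_path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls in np.unique(emb.labels):
        m = emb.labels == cls
        ax.scatter(emb.points[m, 0], emb.points[m, 1], s=12, label=str(cls))
    ax.legend(fontsize=7, markerscale=1.5)
    ax.set_xticks([])
    ax.set_yticks([])
    return _save(fig, out_path)


def render(obj, out_path, **kw) -> Path:
    """Dispatch on object type (trace / PCA coords / embedding)."""
    if isinstance(obj, MemoryTrace):
        return render_trace(obj, out_path, **kw)
    if isinstance(obj, dict):
        return render_signature_plane(obj, out_path)
    if isinstance(obj, EmbeddingSet):
        return render_embedding(obj, out_path)
    raise ValidationError(f"cannot render {type(obj)}")
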