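"""Dataset splitting, training loop, and evaluation statistics.

The splitting scheme mirrors the study protocol: a stratified 80/10/10
train/validation/test split, plus stratified K-fold resampling (default
K=5) for cross-validated test accuracy.  The folds rotate the validation
part within the non-test pool while the 10% test part stays fixed, so test
data is never touched during model selection.  Training minimizes softmax
cross-entropy with Adam (default learning rate 1e-4, 50 epochs) and the
checkpoint with the best validation accuracy — never the last epoch — is
the one evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import _nn
from .synthetic_audio import ValidationError


@dataclass
class SplitPlan:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, val_idx) per fold
    seed: int

    @property
    def pool(self) -> np.ndarray:
        """Non-test indices (the 80% + 10% pool the folds partition)."""
        return np.concatenate([self.train, self.val])


def make_splits(labels, ratios=(0.8, 0.1, 0.1), k: int = 5,
                seed: int = 0) -> SplitPlan:
    """Stratified 80/10/10 split plus k disjoint stratified folds of the
    non-test pool.  Every class must have at least k samples."""
    y = np.asarray(labels)
    n = y.size
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValidationError(
                f"class {cls!r} has only {cnt} samples, fewer than k={k}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError("ratios must sum to 1")
    idx = np.arange(n)
    pool_idx, test_idx = train_test_split(
        idx, test_size=ratios[2], stratify=y, random_state=seed)
    val_frac = ratios[1] / (ratios[0] + ratios[1])
    train_idx, val_idx = train_test_split(
        pool_idx, test_size=val_frac, stratify=y[pool_idx], random_state=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(pool_idx[tr], pool_idx[va])
             for tr, va in skf.split(pool_idx, y[pool_idx])]
    return SplitPlan(train=np.sort(train_idx), val=np.sort(val_idx),
                     test=np.sort(test_idx), folds=folds, seed=seed)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    target_val_acc: float | None = None  # stop early once reached

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")


@dataclass
class TrainResult:
    best_state: dict
    best_epoch: int
    best_val_acc: float
    log: pd.DataFrame


def _predict(model, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    probs = []
    for i in range(0, len(X), batch_size):
        probs.append(model.forward(X[i:i + batch_size], train=False))
    return np.concatenate(probs, axis=0)


def predict_labels(model, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Argmax predictions; ties break to the lowest class index."""
    return np.argmax(_predict(model, X, batch_size), axis=1)


def accuracy(model, X, y, batch_size: int = 32) -> float:
    return float(np.mean(predict_labels(model, X, batch_size) == np.asarray(y)))


def train_model(model, X: np.ndarray, y: np.ndarray, plan: SplitPlan,
                cfg: TrainConfig) -> TrainResult:
    """Minimize cross-entropy on the plan's training part; select the epoch
    with maximal validation accuracy (ties -> earliest).  ``X`` holds one
    precomputed input per sample (slide stacks for hybrids), ``y`` integer
    class labels."""
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed)
    opt = _nn.Adam(model.param_items(), lr=cfg.learning_rate)
    rows = []
    best = TrainResult(best_state=model.get_state(), best_epoch=0,
                       best_val_acc=-1.0, log=None)
    Xtr, ytr = X[plan.train], y[plan.train]
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(Xtr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            model.zero_grad()
            logits = model.forward_logits(Xtr[sel], train=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, ytr[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = accuracy(model, X[plan.val], y[plan.val], cfg.batch_size)
        train_loss = float(np.mean(losses))
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_acc": val_acc})
        if val_acc > best.best_val_acc:  # strict: ties keep earliest epoch
            best.best_state = model.get_state()
            best.best_epoch = epoch
            best.best_val_acc = val_acc
        if cfg.target_val_acc is not None and val_acc >= cfg.target_val_acc:
            break
    model.set_state(best.best_state)
    best.log = pd.DataFrame(rows)
    return best


@dataclass
class EvalReport:
    overall_accuracy: float
    per_class_accuracy: dict
    band_histogram: dict
    fold_accuracies: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": {str(k): v
                                   for k, v in self.per_class_accuracy.items()},
            "band_histogram": {str(k): v for k, v in self.band_histogram.items()},
            "fold_accuracies": list(self.fold_accuracies),
        }


def band_histogram(per_class_acc: dict, n_bands: int = 10) -> dict:
    """Count classes per accuracy bracket (default deciles); the counts sum
    to the number of classes present."""
    edges = np.linspace(0, 1, n_bands + 1)
    hist = {}
    for b in range(n_bands):
        lo, hi = edges[b], edges[b + 1]
        label = f"[{lo:.1f},{hi:.1f}" + ("]" if b == n_bands - 1 else ")")
        if b == n_bands - 1:
            cnt = sum(1 for a in per_class_acc.values() if lo <= a <= hi)
        else:
            cnt = sum(1 for a in per_class_acc.values() if lo <= a < hi)
        hist[label] = cnt
    return hist


def evaluate(model, X: np.ndarray, y: np.ndarray, batch_size: int = 32,
             n_bands: int = 10) -> EvalReport:
    """Overall accuracy (argmax, lowest-index tie-break), per-class accuracy
    over each class's test samples, and the class-count-per-accuracy-band
    histogram.  Classes absent from the test set are omitted, not zeroed."""
    y = np.asarray(y)
    pred = predict_labels(model, X, batch_size)
    overall = float(np.mean(pred == y))
    per_class = {}
    for cls in np.unique(y):
        mask = y == cls
        per_class[int(cls)] = float(np.mean(pred[mask] == cls))
    return EvalReport(overall_accuracy=overall, per_class_accuracy=per_class,
                      band_histogram=band_histogram(per_class, n_bands))


def cross_validate(model_factory, X: np.ndarray, y: np.ndarray,
                   plan: SplitPlan, cfg: TrainConfig) -> dict:
    """Train one fresh model per fold (validation part rotating within the
    pool, test part fixed) and average test accuracy across folds.

    ``model_factory(fold_index)`` must return a fresh untrained model."""
    y = np.asarray(y)
    accs = []
    for f, (tr, va) in enumerate(plan.folds):
        fold_plan = SplitPlan(train=tr, val=va, test=plan.test,
                              folds=plan.folds, seed=plan.seed)
        model = model_factory(f)
        train_model(model, X, y, fold_plan, cfg)
        accs.append(accuracy(model, X[plan.test], y[plan.test],
                             cfg.batch_size))
    return {"fold_accuracies": accs, "mean": float(np.mean(accs)),
            "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0}
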