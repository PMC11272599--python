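"""Dataset splitting, training, the per-class metric suite, cross-validation and sweeps.

Evaluation reports, for each class treated one-vs-rest: precision TP/(TP+FP),
recall (sensitivity) TP/(TP+FN), specificity TN/(TN+FP) and F1, plus their
unweighted (macro) averages, overall accuracy, and per-class ROC curves with
trapezoidal AUC computed from the softmax scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix as _confusion
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from shockscale._layers import Adam, Sequential, cross_entropy
from shockscale.net import ModelConfig, build_model
from shockscale.scalogram import (
    CWTTransformer,
    MorletConfig,
    ScaleGrid,
    normalize_for_model,
    render,
)
from shockscale.types import ECGFragment


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class ImageSet:
    """Model-ready images: X (N, H, W, 3) floats in [0, 1], int labels, ids."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    label_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray | list[int]) -> "ImageSet":
        idx = np.asarray(idx)
        return ImageSet(self.X[idx], self.y[idx], [self.ids[i] for i in idx], self.label_names)


def build_image_set(
    fragments: list[ECGFragment],
    grid: ScaleGrid | None = None,
    wavelet: MorletConfig | None = None,
    size: int = 227,
    colormap: str = "jet",
    log_magnitude: bool = False,
) -> ImageSet:
    """Transform labeled fragments into normalized scalogram images.

    All fragments must share length and sampling rate (the kernel FFTs are
    cached across the batch).
    """
    if not fragments:
        raise ValueError("no fragments to convert")
    wavelet = wavelet or MorletConfig()
    if grid is None:
        grid = ScaleGrid.from_frequencies(1.0, 50.0, 64, wavelet.center_frequency)
    labels = sorted({f.label for f in fragments})
    if None in labels:
        raise ValueError("all fragments must be labeled")
    tr = CWTTransformer(len(fragments[0].samples), fragments[0].fs, grid, wavelet)
    X = np.empty((len(fragments), size, size, 3), dtype=np.float32)
    y = np.empty(len(fragments), dtype=np.int64)
    ids = []
    for i, f in enumerate(fragments):
        img = render(tr.transform(f), size=size, colormap=colormap, log_magnitude=log_magnitude)
        X[i] = normalize_for_model(img)
        y[i] = labels.index(f.label)
        ids.append(f.id)
    return ImageSet(X=X, y=y, ids=ids, label_names=tuple(labels))


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Train/val/test ratios (must sum to 1), stratification flag and seed."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios) or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must be non-negative and sum to 1")


def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (train, val, test) index partition.

    Per stratum: ``n_val = round(n * val_ratio)``, ``n_test = round(n *
    test_ratio)``, remainder to train.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    strata = [np.flatnonzero(labels == v) for v in np.unique(labels)] if spec.stratified else [np.arange(len(labels))]
    train, val, test = [], [], []
    for idx in strata:
        perm = idx[rng.permutation(len(idx))]
        n = len(perm)
        n_val = int(round(n * spec.ratios[1]))
        n_test = int(round(n * spec.ratios[2]))
        n_train = n - n_val - n_test
        train.append(perm[:n_train])
        val.append(perm[n_train : n_train + n_val])
        test.append(perm[n_train + n_val :])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(val)), np.sort(np.concatenate(test)))


def split_dataset(
    fragments: list[ECGFragment], spec: SplitSpec
) -> tuple[list[ECGFragment], list[ECGFragment], list[ECGFragment]]:
    """Split fragments into disjoint (train, val, test) lists."""
    labels = np.array([f.label for f in fragments])
    tr, va, te = split_indices(labels, spec)
    pick = lambda idx: [fragments[i] for i in idx]
    return pick(tr), pick(va), pick(te)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Adam optimisation settings: learning rate 0.001 with legacy per-step
    decay 1e-6, batch size 16, categorical cross-entropy; 400 epochs by
    default (scale down for desk-size runs)."""

    learning_rate: float = 0.001
    decay: float = 1e-6
    batch_size: int = 16
    epochs: int = 400
    seed: int = 0
    checkpoint: str = "best"  # "best" (val accuracy) or "last"

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")
        if self.checkpoint not in ("best", "last"):
            raise ValueError("checkpoint must be 'best' or 'last'")


def _dataset_metrics(model: Sequential, ds: ImageSet, batch_size: int) -> tuple[float, float]:
    probs = model.predict_proba(ds.X, batch_size=batch_size)
    loss = cross_entropy(probs, ds.y)
    acc = float(np.mean(probs.argmax(axis=1) == ds.y))
    return loss, acc


def train(
    model: Sequential,
    train_set: ImageSet,
    val_set: ImageSet | None,
    cfg: TrainConfig,
) -> list[dict]:
    """Train in place; returns one history row per epoch.

    Rows carry epoch index, mean train loss/accuracy over the epoch's batches
    and end-of-epoch validation loss/accuracy.  With ``checkpoint="best"`` the
    weights of the best-validation-accuracy epoch (earliest on ties) are
    restored at the end.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if int(train_set.y.max(initial=0)) >= model.layers[-1].params["b"].shape[0]:
        raise ValueError("label outside the model's class set")
    opt = Adam(model, lr=cfg.learning_rate, decay=cfg.decay)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_acc, best_weights = -1.0, None
    n = len(train_set)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, probs = model.loss_and_grads(train_set.X[idx], train_set.y[idx], train=True)
            opt.step()
            losses.append(loss * len(idx))
            hits += int(np.sum(probs.argmax(axis=1) == train_set.y[idx]))
            seen += len(idx)
        row = {
            "epoch": epoch,
            "train_loss": float(np.sum(losses) / seen),
            "train_acc": hits / seen,
        }
        if val_set is not None and len(val_set):
            row["val_loss"], row["val_acc"] = _dataset_metrics(model, val_set, cfg.batch_size * 4)
            if row["val_acc"] > best_acc:
                best_acc, best_weights = row["val_acc"], model.get_weights()
        history.append(row)
    if cfg.checkpoint == "best" and best_weights is not None:
        model.set_weights(best_weights)
    return history


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix (rows=true, cols=predicted), per-class and macro
    precision/recall/specificity/F1, overall accuracy, per-class ROC/AUC."""

    confusion: np.ndarray
    label_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    accuracy: float
    loss: float
    roc: dict = field(default_factory=dict)  # label -> {"fpr": ..., "tpr": ..., "auc": ...}

    @property
    def macro_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def macro_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def macro_specificity(self) -> float:
        return float(np.mean(self.specificity))

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.f1))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.label_names),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "loss": self.loss,
            "per_class": {
                lab: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "specificity": float(self.specificity[i]),
                    "f1": float(self.f1[i]),
                    "auc": float(self.roc[lab]["auc"]) if lab in self.roc else None,
                }
                for i, lab in enumerate(self.label_names)
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "specificity": self.macro_specificity,
                "f1": self.macro_f1,
            },
        }


def metrics_from_confusion(cm: np.ndarray) -> dict[str, np.ndarray | float]:
    """Per-class one-vs-rest precision/recall/specificity/F1 and accuracy.

    Undefined ratios (empty denominators) are reported as 0.
    """
    cm = np.asarray(cm, dtype=np.int64)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        specificity = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    accuracy = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "accuracy": accuracy,
    }


def evaluate(model: Sequential, test_set: ImageSet, batch_size: int = 64) -> EvalReport:
    """Full metric suite on a held-out set."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    probs = model.predict_proba(test_set.X, batch_size=batch_size)
    return report_from_scores(probs, test_set.y, test_set.label_names)


def report_from_scores(probs: np.ndarray, y: np.ndarray, label_names: tuple[str, ...]) -> EvalReport:
    """Build an :class:`EvalReport` from softmax scores and true labels."""
    k = len(label_names)
    pred = probs.argmax(axis=1)
    cm = _confusion(y, pred, labels=np.arange(k))
    m = metrics_from_confusion(cm)
    roc = {}
    for i, lab in enumerate(label_names):
        binary = (y == i).astype(int)
        if binary.min() == binary.max():  # degenerate: one class absent
            roc[lab] = {"fpr": np.array([0.0, 1.0]), "tpr": np.array([0.0, 1.0]), "auc": 0.5}
            continue
        fpr, tpr, _ = _roc_curve(binary, probs[:, i])
        roc[lab] = {"fpr": fpr, "tpr": tpr, "auc": float(_auc(fpr, tpr))}
    return EvalReport(
        confusion=cm,
        label_names=tuple(label_names),
        precision=m["precision"],
        recall=m["recall"],
        specificity=m["specificity"],
        f1=m["f1"],
        accuracy=m["accuracy"],
        loss=cross_entropy(probs, y),
        roc=roc,
    )


# ---------------------------------------------------------------------------
# Cross-validation and hyperparameter sweep
# ---------------------------------------------------------------------------

def cross_validate(
    images: ImageSet,
    k: int = 5,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> dict:
    """Stratified k-fold: each sample is tested exactly once.

    Per fold a fresh model is trained on the other k-1 folds (last-epoch
    weights; no extra validation split) and scored on the held-out fold.
    Returns ``{"folds": [{"fold", "accuracy", "loss"}...], "mean_accuracy",
    "mean_loss"}``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(images.X, images.y), start=1):
        model = build_model(model_cfg, seed=seed + fold)
        fold_cfg = replace(train_cfg, checkpoint="last", seed=train_cfg.seed + fold)
        train(model, images.subset(tr_idx), None, fold_cfg)
        report = evaluate(model, images.subset(te_idx))
        folds.append({"fold": fold, "accuracy": report.accuracy, "loss": report.loss})
    return {
        "folds": folds,
        "mean_accuracy": float(np.mean([f["accuracy"] for f in folds])),
        "mean_loss": float(np.mean([f["loss"] for f in folds])),
    }


def sweep(
    train_set: ImageSet,
    val_set: ImageSet,
    grid: dict[str, list],
    model_cfg: ModelConfig | None = None,
    base_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """One seeded train/eval per grid cell over {learning_rate, decay, batch_size}.

    Rows are sorted by validation accuracy descending, ties by smaller batch
    size; the best row is flagged.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    model_cfg = model_cfg or ModelConfig()
    base_cfg = base_cfg or TrainConfig()
    keys = ("learning_rate", "decay", "batch_size")
    values = [grid.get(k, [getattr(base_cfg, k)]) for k in keys]
    rows = []
    for lr, decay, batch in itertools.product(*values):
        cfg = replace(base_cfg, learning_rate=float(lr), decay=float(decay), batch_size=int(batch))
        model = build_model(model_cfg, seed=seed)
        train(model, train_set, val_set, cfg)
        _, val_acc = _dataset_metrics(model, val_set, 64)
        rows.append(
            {"learning_rate": lr, "decay": decay, "batch_size": batch, "val_accuracy": val_acc}
        )
    rows.sort(key=lambda r: (-r["val_accuracy"], r["batch_size"]))
    for i, r in enumerate(rows):
        r["best"] = i == 0
    return rows
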