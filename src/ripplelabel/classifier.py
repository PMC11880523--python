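"""Supervised 1-D CNN and the cross-validation harness.

Every experimental arm — original noisy labels, SSL-derived group labels,
or the intersection subset — is trained inside the same stratified 5-fold
protocol and always *evaluated against the original observed labels* of the
held-out fold, so accuracies are comparable across arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from . import nn
from .autodiff import Tensor
from .relabel import RelabelResult
from .simulate import LabeledDataset

__all__ = [
    "CNNConfig",
    "CVResult",
    "CNN1D",
    "build_cnn",
    "fit",
    "predict",
    "evaluate",
    "cross_validate",
    "LABEL_SOURCES",
]

LABEL_SOURCES = ("original", "true_class", "ssl_groups", "intersection")


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training settings of the 1-D CNN.

    Three convolution blocks (conv -> batch norm -> ReLU -> max-pool 2)
    feed a dropout + dense classifier head with a 2-way softmax output.
    """

    input_length: int = 512
    conv_filters: tuple[int, ...] = (64, 128, 256)
    kernel_sizes: tuple[int, ...] = (7, 5, 3)
    pool_size: int = 2
    dropout: float = 0.5
    dense_units: int = 128
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_filters) != len(self.kernel_sizes):
            raise ValueError("one kernel size per conv block")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class CNN1D(nn.Module):
    """Conv blocks + dropout + dense + 2-way softmax over a 512-sample RCI."""

    def __init__(self, cfg: CNNConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        layers: list[nn.Module] = []
        channels = 1
        length = cfg.input_length
        for filters, kernel in zip(cfg.conv_filters, cfg.kernel_sizes):
            layers += [
                nn.Conv1d(channels, filters, kernel, rng),
                nn.BatchNorm1d(filters),
                nn.ReLU(),
                nn.MaxPool1d(cfg.pool_size),
            ]
            channels = filters
            if length % cfg.pool_size:
                raise ValueError("input length not divisible by the pooling chain")
            length //= cfg.pool_size
        self.blocks = nn.Sequential(*layers)
        self.flatten = nn.Flatten()
        self.dropout = nn.Dropout(cfg.dropout, rng)
        self.dense = nn.Linear(channels * length, cfg.dense_units, rng)
        self.head = nn.Linear(cfg.dense_units, 2, rng)

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """Class logits for a (batch, length) matrix of windows."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 2 or x.shape[1] != self.cfg.input_length:
            raise ValueError(f"expected (batch, {self.cfg.input_length}) input")
        h = self.blocks(x.reshape(x.shape[0], x.shape[1], 1))
        h = self.dropout(self.flatten(h))
        return self.head(self.dense(h).relu())

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities (rows sum to 1), evaluation mode."""
        was_training = self.training
        self.eval()
        out = nn.softmax(self.forward(x)).numpy()
        self.train(was_training)
        return out

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_cnn(cfg: CNNConfig) -> CNN1D:
    """Construct a CNN with weights drawn from ``cfg.seed``."""
    return CNN1D(cfg, np.random.default_rng(cfg.seed))


def fit(
    model: CNN1D,
    x: np.ndarray,
    y: np.ndarray,
    cfg: CNNConfig,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Minibatch Adam training on integer labels; returns epoch losses."""
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = rng or np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = []
    n = len(x)
    bs = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            if len(idx) < 2:  # batch norm needs at least 2 rows
                continue
            logits = model(x[idx])
            loss = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history


def predict(model: CNN1D, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Argmax class predictions in evaluation mode."""
    preds = []
    for start in range(0, len(x), batch_size):
        preds.append(model.predict_proba(x[start : start + batch_size]).argmax(axis=1))
    return np.concatenate(preds)


def evaluate(model: CNN1D, x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 of argmax predictions."""
    if len(x) == 0:
        raise ValueError("empty test set")
    y = np.asarray(y, dtype=np.int64)
    pred = predict(model, x)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y, pred, average="macro", zero_division=0
    )
    return {
        "accuracy": float(np.mean(pred == y)),
        "f1": float(f1),
        "precision": float(precision),
        "recall": float(recall),
    }


@dataclass
class CVResult:
    """Per-fold metrics of one cross-validated arm."""

    label_source: str
    per_fold_accuracy: np.ndarray
    per_fold_f1: np.ndarray
    per_fold_precision: np.ndarray
    per_fold_recall: np.ndarray
    train_sizes: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def sem(self) -> float:
        k = len(self.per_fold_accuracy)
        return float(np.std(self.per_fold_accuracy, ddof=1) / np.sqrt(k))

    @property
    def f1(self) -> float:
        return float(np.mean(self.per_fold_f1))

    @property
    def precision(self) -> float:
        return float(np.mean(self.per_fold_precision))

    @property
    def recall(self) -> float:
        return float(np.mean(self.per_fold_recall))

    def to_dict(self) -> dict:
        return {
            "label_source": self.label_source,
            "per_fold_accuracy": self.per_fold_accuracy.tolist(),
            "mean_accuracy": self.mean,
            "sem": self.sem,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "train_sizes": self.train_sizes.tolist(),
        }


def _training_labels(
    dataset: LabeledDataset,
    label_source: str,
    relabel_result: RelabelResult | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label vector and row mask used for training under each arm."""
    n = len(dataset)
    keep = np.ones(n, dtype=bool)
    if label_source == "original":
        labels = dataset.observed_label
    elif label_source == "true_class":
        labels = dataset.true_class
    elif label_source == "ssl_groups":
        if relabel_result is None:
            raise ValueError("ssl_groups arm needs a RelabelResult")
        labels = relabel_result.group  # aligned: G1 -> BL code, G2 -> AL code
    elif label_source == "intersection":
        if relabel_result is None:
            raise ValueError("intersection arm needs a RelabelResult")
        labels = dataset.observed_label
        keep = relabel_result.intersection_mask.copy()
    else:
        raise ValueError(f"unknown label source {label_source!r}")
    return np.asarray(labels, dtype=np.int64), keep


def cross_validate(
    dataset: LabeledDataset,
    label_source: str,
    cfg: CNNConfig,
    relabel_result: RelabelResult | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold evaluation of one labeling arm.

    Folds are stratified on the *observed* labels, the training labels come
    from the arm (``original``, ``true_class``, ``ssl_groups`` or
    ``intersection``), and the held-out fold is always scored against the
    observed labels.
    """
    x = dataset.signals
    observed = np.asarray(dataset.observed_label, dtype=np.int64)
    train_labels, keep = _training_labels(dataset, label_source, relabel_result)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc, f1s, precs, recs, sizes = [], [], [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(x, observed)):
        train_idx = train_idx[keep[train_idx]]
        if len(np.unique(train_labels[train_idx])) < 2:
            raise ValueError("training fold lost a class")
        model = CNN1D(cfg, np.random.default_rng((cfg.seed, seed, fold)))
        fit(
            model,
            x[train_idx],
            train_labels[train_idx],
            cfg,
            np.random.default_rng((cfg.seed, seed, fold, 1)),
        )
        metrics = evaluate(model, x[test_idx], observed[test_idx])
        acc.append(metrics["accuracy"])
        f1s.append(metrics["f1"])
        precs.append(metrics["precision"])
        recs.append(metrics["recall"])
        sizes.append(len(train_idx))
    return CVResult(
        label_source,
        np.array(acc),
        np.array(f1s),
        np.array(precs),
        np.array(recs),
        np.array(sizes),
    )
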