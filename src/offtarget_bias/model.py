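"""Imbalance-weighted feed-forward binary classifier on fingerprints.

A single-hidden-layer network (ReLU hidden, sigmoid output) trained with
class-weighted binary cross-entropy: misclassifying the minority class
costs more than misclassifying the majority class, the standard remedy for
the strong class skew of activity datasets.  Training uses Adam at an
initial learning rate of 0.01, a 0.1 learning-rate cut when the training
loss plateaus for 10 epochs, and early stopping after 20 epochs without
training-loss improvement; the classification threshold on the output
probability is fixed at 0.5 (a probability of exactly 0.5 is called
active).

Hyperparameters are tuned by a full grid search — hidden units 256..2048
(step 256), input dropout 0..0.2 and hidden dropout 0.2..0.4 (step 0.1),
batch size 64..256 (step 64), a 288-point grid — on a stratified 80/20
training/validation split, selecting the model with the best validation
MCC.  The trainer itself is a small NumPy implementation, which keeps
training deterministic for a fixed seed on any platform.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from offtarget_bias.curation import LabeledDataset
from offtarget_bias.metrics import (
    UNDEFINED,
    MetricReport,
    compute_metrics,
    confusion_from_calls,
)

__all__ = [
    "TrainConfig",
    "HyperGrid",
    "ClassifierArtifact",
    "weighted_bce",
    "class_weights_from_counts",
    "train_classifier",
    "grid_search",
    "cross_validate",
    "predict",
]

_EPS = 1e-7


def weighted_bce(
    y_true: np.ndarray, p: np.ndarray, weights: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Class-weighted binary cross-entropy.

    ``mean(-(w_pos * y * log p + w_neg * (1 - y) * log(1 - p)))`` with
    ``weights = (w_neg, w_pos)``.  At weights (1, 1) this is exactly the
    unweighted BCE.  Probabilities are clipped away from {0, 1}.
    """
    y = np.asarray(y_true, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    if y.shape != p.shape:
        raise ValueError("y_true and p must have the same length")
    w_neg, w_pos = weights
    return float(np.mean(-(w_pos * y * np.log(p) + w_neg * (1.0 - y) * np.log(1.0 - p))))


def class_weights_from_counts(n_neg: int, n_pos: int) -> tuple[float, float]:
    """Balanced inverse-frequency loss weights ``w_c = N / (2 * N_c)``.

    The minority class receives the larger weight; at perfect balance both
    weights are 1 and the loss reduces to unweighted BCE.
    """
    if n_neg <= 0 or n_pos <= 0:
        raise ValueError(
            "both classes must be present to train a classifier "
            f"(got n_neg={n_neg}, n_pos={n_pos})"
        )
    total = n_neg + n_pos
    return (total / (2.0 * n_neg), total / (2.0 * n_pos))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the package's study settings)."""

    hidden_units: int = 256
    dropout_input: float = 0.0
    dropout_hidden: float = 0.2
    batch_size: int = 128
    learning_rate: float = 0.01
    lr_patience: int = 10
    stop_patience: int = 20
    lr_factor: float = 0.1
    min_lr: float = 1e-5
    max_epochs: int = 500
    class_weights: tuple[float, float] | None = None  # None -> from counts
    seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not (0 <= self.dropout_input < 1 and 0 <= self.dropout_hidden < 1):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_patience < 1 or self.stop_patience < 1:
            raise ValueError("patiences must be positive")


@dataclass(frozen=True)
class HyperGrid:
    """Cartesian hyperparameter grid; the default expands to 288 points."""

    hidden_units: tuple[int, ...] = tuple(range(256, 2049, 256))
    dropout_input: tuple[float, ...] = (0.0, 0.1, 0.2)
    dropout_hidden: tuple[float, ...] = (0.2, 0.3, 0.4)
    batch_size: tuple[int, ...] = tuple(range(64, 257, 64))

    def __len__(self) -> int:
        return (
            len(self.hidden_units)
            * len(self.dropout_input)
            * len(self.dropout_hidden)
            * len(self.batch_size)
        )

    def expand(self) -> list[dict]:
        return [
            {
                "hidden_units": h,
                "dropout_input": di,
                "dropout_hidden": dh,
                "batch_size": b,
            }
            for h, di, dh, b in itertools.product(
                self.hidden_units, self.dropout_input, self.dropout_hidden, self.batch_size
            )
        ]


class _Network:
    """One-hidden-layer MLP with inverted dropout and Adam, NumPy-only."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        # He initialization for the ReLU layer, Xavier for the output.
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_hidden)).astype(np.float32)
        self.b1 = np.zeros(n_hidden, dtype=np.float32)
        self.w2 = rng.normal(0.0, np.sqrt(1.0 / n_hidden), (n_hidden, 1)).astype(np.float32)
        self.b2 = np.zeros(1, dtype=np.float32)
        self._adam_m = [np.zeros_like(p) for p in self.params]
        self._adam_v = [np.zeros_like(p) for p in self.params]
        self._adam_t = 0

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        z = h @ self.w2 + self.b2
        return 1.0 / (1.0 + np.exp(-z[:, 0]))

    def train_step(
        self,
        x: np.ndarray,
        y: np.ndarray,
        weights: tuple[float, float],
        lr: float,
        dropout: tuple[float, float],
        rng: np.random.Generator,
    ) -> None:
        d_in, d_hid = dropout
        if d_in > 0:
            mask = (rng.random(x.shape) >= d_in).astype(np.float32) / (1.0 - d_in)
            x = x * mask
        h_pre = x @ self.w1 + self.b1
        h = np.maximum(h_pre, 0.0)
        if d_hid > 0:
            mask_h = (rng.random(h.shape) >= d_hid).astype(np.float32) / (1.0 - d_hid)
            h = h * mask_h
        z = h @ self.w2 + self.b2
        p = 1.0 / (1.0 + np.exp(-z[:, 0]))
        w_neg, w_pos = weights
        # d(weighted BCE)/dz for the sigmoid output
        sample_w = np.where(y == 1, w_pos, w_neg).astype(np.float32)
        dz = (sample_w * (p - y) / len(y)).astype(np.float32)[:, None]
        gw2 = h.T @ dz
        gb2 = dz.sum(axis=0)
        dh = dz @ self.w2.T
        if d_hid > 0:
            dh = dh * mask_h
        dh = dh * (h_pre > 0)
        gw1 = x.T @ dh
        gb1 = dh.sum(axis=0)
        self._adam_t += 1
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for param, grad, m, v in zip(
            self.params, [gw1, gb1, gw2, gb2], self._adam_m, self._adam_v
        ):
            m[...] = beta1 * m + (1 - beta1) * grad
            v[...] = beta2 * v + (1 - beta2) * grad**2
            m_hat = m / (1 - beta1**self._adam_t)
            v_hat = v / (1 - beta2**self._adam_t)
            param -= lr * m_hat / (np.sqrt(v_hat) + eps)


@dataclass
class ClassifierArtifact:
    """A trained classifier with its config, history and selection metrics.

    ``predict_proba`` is deterministic (inference applies no dropout);
    binary calls use the fixed 0.5 threshold, boundary inclusive.
    """

    config: TrainConfig
    network: _Network
    n_features: int
    classification_threshold: float = 0.5
    training_history: list[dict] = field(default_factory=list)
    selection_metrics: MetricReport | None = None
    class_weights: tuple[float, float] = (1.0, 1.0)

    def predict_proba(self, fingerprints: np.ndarray) -> np.ndarray:
        x = np.asarray(fingerprints, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError(
                f"fingerprint dimension {x.shape} does not match training dimension "
                f"{self.n_features}"
            )
        return self.network.forward(x).astype(np.float64)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cfg = dataclasses.asdict(self.config)
        meta = {
            "config": cfg,
            "n_features": self.n_features,
            "classification_threshold": self.classification_threshold,
            "class_weights": list(self.class_weights),
            "training_history": self.training_history,
        }
        (path / "config.json").write_text(json.dumps(meta, indent=1))
        np.savez(
            path / "weights.npz",
            w1=self.network.w1,
            b1=self.network.b1,
            w2=self.network.w2,
            b2=self.network.b2,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierArtifact":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        cfg = meta["config"]
        cfg["class_weights"] = tuple(cfg["class_weights"]) if cfg["class_weights"] else None
        config = TrainConfig(**cfg)
        weights = np.load(path / "weights.npz")
        net = _Network.__new__(_Network)
        net.w1, net.b1 = weights["w1"], weights["b1"]
        net.w2, net.b2 = weights["w2"], weights["b2"]
        net._adam_m = [np.zeros_like(p) for p in net.params]
        net._adam_v = [np.zeros_like(p) for p in net.params]
        net._adam_t = 0
        return cls(
            config=config,
            network=net,
            n_features=meta["n_features"],
            classification_threshold=meta["classification_threshold"],
            training_history=meta["training_history"],
            class_weights=tuple(meta["class_weights"]),
        )


def train_classifier(
    x: np.ndarray, y: np.ndarray, config: TrainConfig = TrainConfig()
) -> ClassifierArtifact:
    """Train the network on (fingerprints, 0/1 labels).

    Loss weights default to balanced inverse-frequency weights from the
    training counts.  After every epoch the full-training-set loss (without
    dropout) is recorded; the learning rate is multiplied by ``lr_factor``
    when that loss has not improved for ``lr_patience`` epochs (floor
    ``min_lr``) and training stops after ``stop_patience`` epochs without
    improvement, or at ``max_epochs``.  Fully deterministic per seed.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("x must be 2D and parallel to y")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    weights = config.class_weights or class_weights_from_counts(n_neg, n_pos)
    rng = np.random.default_rng(config.seed)
    net = _Network(x.shape[1], config.hidden_units, rng)
    lr = config.learning_rate
    best_loss = np.inf
    epochs_since_best = 0
    epochs_since_lr_cut = 0
    history: list[dict] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(x), config.batch_size):
            batch = order[start : start + config.batch_size]
            net.train_step(
                x[batch],
                y[batch],
                weights,
                lr,
                (config.dropout_input, config.dropout_hidden),
                rng,
            )
        loss = weighted_bce(y, net.forward(x), weights)
        history.append({"epoch": epoch, "loss": loss, "lr": lr})
        if loss < best_loss - 1e-6:
            best_loss = loss
            epochs_since_best = 0
            epochs_since_lr_cut = 0
        else:
            epochs_since_best += 1
            epochs_since_lr_cut += 1
        if epochs_since_best >= config.stop_patience:
            break
        if epochs_since_lr_cut >= config.lr_patience and lr > config.min_lr:
            lr = max(lr * config.lr_factor, config.min_lr)
            epochs_since_lr_cut = 0
    return ClassifierArtifact(
        config=config,
        network=net,
        n_features=x.shape[1],
        training_history=history,
        class_weights=weights,
    )


def predict(
    artifact: ClassifierArtifact, fingerprints: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and binary calls at the fixed 0.5 threshold.

    A probability exactly at 0.5 is called active (>= convention).
    Inference is dropout-free and therefore deterministic.
    """
    proba = artifact.predict_proba(fingerprints)
    calls = (proba >= artifact.classification_threshold).astype(int)
    return proba, calls


def _mcc_key(report: MetricReport) -> tuple[float, float]:
    mcc = report.mcc if report.mcc is not UNDEFINED else -np.inf
    ba = report.balanced_accuracy if report.balanced_accuracy is not UNDEFINED else -np.inf
    return (mcc, ba)


def grid_search(
    dataset: LabeledDataset | tuple[np.ndarray, np.ndarray],
    grid: HyperGrid = HyperGrid(),
    seed: int = 0,
    base_config: TrainConfig | None = None,
    fingerprints: np.ndarray | None = None,
) -> tuple[ClassifierArtifact, pd.DataFrame]:
    """Exhaustive grid search selected by validation MCC.

    One model is trained per grid point on a stratified 80% split and
    evaluated on the held-out 20% validation split (the same split for all
    points).  Returns the artifact with the highest validation MCC — ties
    broken by higher balanced accuracy, then fewer hidden units, then
    smaller batch size — plus a DataFrame with one row per grid point
    (config columns + validation metrics), reproducible for a fixed seed.

    ``dataset`` may be a :class:`LabeledDataset` (with ``fingerprints``
    row-aligned to it) or a plain ``(X, y)`` tuple.
    """
    if isinstance(dataset, LabeledDataset):
        if fingerprints is None:
            raise ValueError("fingerprints required when passing a LabeledDataset")
        x = np.asarray(fingerprints, dtype=np.float32)
        y = np.asarray(dataset.labels, dtype=int)
    else:
        x, y = dataset
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    base = base_config or TrainConfig()
    x_tr, x_val, y_tr, y_val = train_test_split(
        x, y, test_size=base.validation_fraction, stratify=y, random_state=seed
    )
    if len(np.unique(y_val)) < 2 or len(np.unique(y_tr)) < 2:
        raise ValueError("degenerate stratified split: a side has a single class")
    rows = []
    candidates: list[tuple[tuple, int, ClassifierArtifact]] = []
    for i, point in enumerate(grid.expand()):
        config = dataclasses.replace(base, seed=seed, **point)
        artifact = train_classifier(x_tr, y_tr, config)
        _, calls = predict(artifact, x_val)
        report = compute_metrics(confusion_from_calls(y_val, calls))
        artifact.selection_metrics = report
        sort_key = (*_mcc_key(report), -point["hidden_units"], -point["batch_size"])
        candidates.append((sort_key, i, artifact))
        rows.append({**point, **{k: (np.nan if v is UNDEFINED else v) for k, v in report.as_dict().items()}})
    candidates.sort(key=lambda t: (t[0], -t[1]), reverse=True)
    best = candidates[0][2]
    return best, pd.DataFrame(rows)


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    k: int = 5,
    seed: int = 0,
) -> tuple[list[MetricReport], pd.DataFrame]:
    """Stratified k-fold cross-validation at one fixed configuration.

    Each fold trains a fresh model on the other folds and is scored on the
    held-out fold.  Returns the per-fold reports and a mean/SD summary of
    balanced accuracy, accuracy, recall, F-measure and MCC (undefined
    cells excluded from the aggregation as NaN).
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(x, y)):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"fold {fold} does not contain both classes")
        artifact = train_classifier(
            x[train_idx], y[train_idx], dataclasses.replace(config, seed=seed + fold)
        )
        _, calls = predict(artifact, x[test_idx])
        reports.append(compute_metrics(confusion_from_calls(y[test_idx], calls)))
    stats = ["balanced_accuracy", "accuracy", "recall", "f_measure", "mcc"]
    values = {
        s: np.array(
            [np.nan if getattr(r, s) is UNDEFINED else getattr(r, s) for r in reports]
        )
        for s in stats
    }
    summary = pd.DataFrame(
        {
            "metric": stats,
            "mean": [np.nanmean(values[s]) for s in stats],
            "sd": [np.nanstd(values[s], ddof=1) for s in stats],
        }
    )
    return reports, summary
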