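"""Training recipe: stratified splitting, inverse-frequency class weights,
SGD with momentum under a triangular cyclical learning rate, and
minimum-validation-loss model selection.

The class-imbalanced tissue dataset is handled with cross-entropy whose
per-class weights are inversely proportional to class frequency,
``w_c = N / (K * n_c)``; losses are reduced as ``sum(w_i * nll_i) /
sum(w_i)`` so the scale is batch-size independent and collapses exactly to
the unweighted mean when all weights are one.

The learning rate follows a triangular cyclical policy: it ramps linearly
from ``base_lr`` to ``max_lr`` over ``step_size`` iterations and back,
repeating with period ``2 * step_size``. The default schedule sets the
step size to 8 epochs' worth of batches.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .nn.layers import softmax
from .nn.resnet import ResNet1D
from .spectra import LabeledDataset

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "StratificationError",
    "stratified_split",
    "class_weights",
    "clr_schedule",
    "weighted_cross_entropy",
    "SGD",
    "train",
]


class StratificationError(ValueError):
    """Raised when a class is too small to stratify."""


@dataclass
class TrainConfig:
    """Hyperparameters of the training loop.

    Full-scale defaults: 80/20 stratified split, 50 epochs of SGD
    (momentum 0.9) under a triangular cyclical learning rate between
    0.001 and 0.01 with an 8-epoch half-period, batch size 128. A
    stratified ``validation_fraction`` of the training split is held out
    for model selection, never touching the test split.
    """

    split_fraction: float = 0.8
    batch_size: int = 128
    epochs: int = 50
    base_lr: float = 0.001
    max_lr: float = 0.01
    momentum: float = 0.9
    clr_cycle_epochs: int = 8
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.base_lr >= self.max_lr:
            raise ValueError("base_lr must be < max_lr")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "split_fraction": self.split_fraction,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "base_lr": self.base_lr,
            "max_lr": self.max_lr,
            "momentum": self.momentum,
            "clr_cycle_epochs": self.clr_cycle_epochs,
            "seed": self.seed,
            "validation_fraction": self.validation_fraction,
        }


@dataclass
class TrainingHistory:
    """Per-epoch losses, the per-iteration learning-rate trace, and the
    index of the selected (minimum-validation-loss) epoch."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    lr_trace: List[float] = field(default_factory=list)
    selected_epoch: int = -1


def stratified_split(dataset: LabeledDataset, fraction: float,
                     seed: int) -> Tuple[LabeledDataset, LabeledDataset]:
    """Split a dataset per class: ``floor(fraction * n_c)`` spectra to the
    first part (shuffled by ``seed``), the remainder to the second.

    Every class needs at least 2 spectra so both parts can be non-empty
    at the default fraction.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = dataset.labels
    rng = np.random.default_rng(seed)
    train_idx: List[np.ndarray] = []
    test_idx: List[np.ndarray] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise StratificationError(
                f"class {cls!r} has {idx.size} spectrum(s); need >= 2 to stratify"
            )
        perm = rng.permutation(idx)
        n_train = int(np.floor(fraction * idx.size))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = dataset.subset(np.concatenate(train_idx))
    test = dataset.subset(np.concatenate(test_idx))
    return train, test


def class_weights(class_counts: Mapping[str, int]) -> Dict[str, float]:
    """Inverse-frequency weights ``w_c = N / (K * n_c)``.

    Balanced classes get weight 1; the weights are invariant to scaling
    every count by the same factor.
    """
    if not class_counts:
        raise ValueError("class_counts is empty")
    for cls, n in class_counts.items():
        if n <= 0:
            raise ValueError(f"class {cls!r} has non-positive count {n}")
    total = float(sum(class_counts.values()))
    k = len(class_counts)
    return {cls: total / (k * n) for cls, n in class_counts.items()}


def clr_schedule(iteration: int, base_lr: float, max_lr: float,
                 step_size: int) -> float:
    """Triangular cyclical learning rate.

    Piecewise linear: ``lr(0) = base_lr``, ``lr(step_size) = max_lr``,
    ``lr(2 * step_size) = base_lr``, period ``2 * step_size``.
    """
    if base_lr > max_lr:
        raise ValueError("base_lr must be <= max_lr")
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    cycle = np.floor(1 + iteration / (2.0 * step_size))
    x = abs(iteration / float(step_size) - 2.0 * cycle + 1.0)
    return float(base_lr + (max_lr - base_lr) * max(0.0, 1.0 - x))


def weighted_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                           weights: np.ndarray,
                           return_grad: bool = True):
    """Class-weighted cross-entropy on pre-softmax scores.

    ``loss = sum_i w[y_i] * (-log p_i[y_i]) / sum_i w[y_i]``; the gradient
    w.r.t. the logits uses the same normalization. Returns ``loss`` or
    ``(loss, grad)``.
    """
    n = logits.shape[0]
    p = softmax(logits)
    w = weights[targets]
    nll = -np.log(np.clip(p[np.arange(n), targets], 1e-300, None))
    wsum = w.sum()
    loss = float((w * nll).sum() / wsum)
    if not return_grad:
        return loss
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, momentum: float = 0.9):
        self.params = list(params)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v += p.grad
            p.value -= lr * v


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries batch index and lr."""


def _encode_labels(labels: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise KeyError(f"label {exc.args[0]!r} not in class list") from None


def _dataset_loss(model: ResNet1D, x: np.ndarray, y: np.ndarray,
                  weights: np.ndarray, batch_size: int) -> float:
    total, wtotal = 0.0, 0.0
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        yb = y[start : start + batch_size]
        logits = model.forward(xb, training=False)
        p = softmax(logits)
        nll = -np.log(np.clip(p[np.arange(len(yb)), yb], 1e-300, None))
        w = weights[yb]
        total += float((w * nll).sum())
        wtotal += float(w.sum())
    return total / wtotal if wtotal else 0.0


def train(model: ResNet1D, train_set: LabeledDataset, cfg: TrainConfig,
          classes: Optional[Sequence[str]] = None,
          progress: Optional[callable] = None) -> Tuple[ResNet1D, TrainingHistory]:
    """Train a model on a (preprocessed) labeled dataset.

    A stratified ``validation_fraction`` of ``train_set`` is held out for
    model selection; the returned model carries the weights of the epoch
    with the minimum validation loss (earliest epoch on ties). Everything
    — the validation split, batch order, and weight initialization (fixed
    at model build) — is driven by seeds, so identical inputs reproduce
    identical histories on CPU.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if classes is None:
        classes = sorted(set(train_set.labels))
    fit_part, val_part = stratified_split(
        train_set, 1.0 - cfg.validation_fraction, seed=cfg.seed + 1
    )
    counts = fit_part.class_counts()
    wmap = class_weights(counts)
    weights = np.array([wmap.get(c, 0.0) for c in classes])

    x_fit = fit_part.intensities
    y_fit = _encode_labels(fit_part.labels, classes)
    x_val = val_part.intensities
    y_val = _encode_labels(val_part.labels, classes)

    n = x_fit.shape[0]
    batches_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    step_size = cfg.clr_cycle_epochs * batches_per_epoch

    rng = np.random.default_rng(cfg.seed + 2)
    opt = SGD(model.params(), momentum=cfg.momentum)
    history = TrainingHistory()
    best_loss = np.inf
    best_state = None
    iteration = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            lr = clr_schedule(iteration, cfg.base_lr, cfg.max_lr, step_size)
            history.lr_trace.append(lr)
            logits = model.forward(x_fit[idx], training=True)
            loss, grad = weighted_cross_entropy(logits, y_fit[idx], weights)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {nb}, lr {lr:g}"
                )
            model.zero_grad()
            model.backward(grad)
            opt.step(lr)
            epoch_loss += loss
            nb += 1
            iteration += 1
        val_loss = _dataset_loss(model, x_val, y_val, weights, cfg.batch_size)
        history.train_loss.append(epoch_loss / nb)
        history.val_loss.append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            history.selected_epoch = epoch
        if progress is not None:
            progress(epoch, history)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
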