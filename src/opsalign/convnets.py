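"""Compact convolutional EEG decoders and their training procedure.

Two architectures are provided, both operating on single-trial inputs of
shape 1 x n_channels x n_samples (default 1 x 3 x 300, i.e. three
sensorimotor channels at 100 Hz for 3 s):

* **ShallowNet** — temporal convolution (band-pass analog), spatial
  convolution across channels (CSP analog), squaring, average pooling and
  log: a learned log band-power feature extractor ending in a linear
  classifier.
* **EEGNet** — temporal convolution, depthwise spatial convolution with
  depth multiplier 2, then a depthwise-separable temporal convolution, ELU
  activations and two pooling stages.

Training is plain Adam on softmax cross-entropy for a fixed number of epochs
(no early stopping); after every epoch validation accuracy is recorded and
the returned weights are those of the best-validation epoch (earliest on
ties).  Runs are exactly reproducible from the seed, which drives weight
initialization, batch shuffling and dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .signals import TrialSet

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "build_shallownet",
    "build_eegnet",
    "train_model",
    "predict",
    "ShallowNet",
    "EEGNet",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the training procedure.

    batch_size defaults to 16 (the within-subject protocol); cross-subject
    and cross-dataset protocols use 128.
    """

    learning_rate: float = 1e-3
    epochs: int = 120
    batch_size: int = 16
    dropout: float = 0.5
    seed: int = 0
    metric: str = "accuracy"

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("hyperparameters must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainedModel:
    """A fitted network plus its training history and selected epoch."""

    name: str
    net: nn.Sequential
    config: TrainConfig
    history: pd.DataFrame = field(repr=False)
    best_epoch: int = 0

    def history_csv(self, path):
        self.history.to_csv(path, index=False)


def build_shallownet(
    n_channels: int = 3, n_samples: int = 300, n_classes: int = 2, dropout: float = 0.5,
    seed: int = 0, dtype=np.float32
) -> nn.Sequential:
    """ShallowNet: 10 temporal kernels (1x21), 15 spatial kernels (Nc x 1),
    square -> average pool (1x55, stride 15) -> log -> dropout -> linear."""
    rng = np.random.default_rng(seed)
    pooled = (n_samples - 55) // 15 + 1
    if pooled < 1:
        raise ValueError(f"n_samples={n_samples} too short for the (1,55)/(1,15) pooling stage")
    net = nn.Sequential(
        [
            nn.Conv2d(1, 10, (1, 21), padding=(0, 10), rng=rng, first_layer=True, dtype=dtype),
            nn.BatchNorm2d(10, dtype=dtype),
            nn.Conv2d(10, 15, (n_channels, 1), rng=rng, dtype=dtype),
            nn.BatchNorm2d(15, dtype=dtype),
            nn.Square(),
            nn.AvgPool1dTime(55, 15),
            nn.LogClip(1e-6),
            nn.Dropout(dropout),
            nn.Flatten(),
            nn.Linear(15 * pooled, n_classes, rng=rng, dtype=dtype),
        ]
    )
    _check_shapes(net, (1, n_channels, n_samples), "shallownet")
    return net


def build_eegnet(
    n_channels: int = 3, n_samples: int = 300, n_classes: int = 2, dropout: float = 0.5,
    seed: int = 0, dtype=np.float32
) -> nn.Sequential:
    """EEGNet: 8 temporal kernels (1x31), depthwise spatial conv (depth
    multiplier 2 -> 16), pool /4, separable conv (1x15), pool /8, linear."""
    rng = np.random.default_rng(seed)
    p1 = n_samples // 4
    p2 = p1 // 8
    if p2 < 1:
        raise ValueError(f"n_samples={n_samples} too short for the /4 then /8 pooling stages")
    net = nn.Sequential(
        [
            nn.Conv2d(1, 8, (1, 31), padding=(0, 15), rng=rng, first_layer=True, dtype=dtype),
            nn.BatchNorm2d(8, dtype=dtype),
            nn.Conv2d(8, 16, (n_channels, 1), groups=8, rng=rng, dtype=dtype),  # depthwise x2
            nn.BatchNorm2d(16, dtype=dtype),
            nn.ELU(),
            nn.AvgPool1dTime(4, 4),
            nn.Dropout(dropout),
            nn.Conv2d(16, 16, (1, 15), padding=(0, 7), groups=16, rng=rng, dtype=dtype),
            nn.Conv2d(16, 16, (1, 1), rng=rng, dtype=dtype),  # separable: pointwise mix
            nn.BatchNorm2d(16, dtype=dtype),
            nn.ELU(),
            nn.AvgPool1dTime(8, 8),
            nn.Dropout(dropout),
            nn.Flatten(),
            nn.Linear(16 * p2, n_classes, rng=rng, dtype=dtype),
        ]
    )
    _check_shapes(net, (1, n_channels, n_samples), "eegnet")
    return net


def _check_shapes(net: nn.Sequential, in_shape, name: str):
    shapes = net.shape_trace(in_shape)
    for layer, s_in, s_out in zip(net.layers, shapes[:-1], shapes[1:]):
        if any(d < 1 for d in s_out):
            raise ValueError(
                f"{name}: layer {type(layer).__name__} maps {s_in} to invalid shape {s_out}"
            )


def _as_input(trials: TrialSet, dtype=np.float32) -> np.ndarray:
    return np.ascontiguousarray(trials.data[:, None, :, :], dtype=dtype)


def _accuracy(net: nn.Sequential, x: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
    correct = 0
    for i in range(0, len(x), batch):
        logits = net.forward(x[i : i + batch], train=False)
        correct += int(np.sum(np.argmax(logits, axis=1) == y[i : i + batch]))
    return correct / len(x)


def train_model(
    net: nn.Sequential,
    train: TrialSet,
    valid: TrialSet,
    config: TrainConfig = TrainConfig(),
    name: str = "convnet",
) -> TrainedModel:
    """Train with Adam + cross-entropy; restore the best-validation epoch.

    One history row per epoch: (epoch, train_loss, valid_accuracy).  The
    returned network carries the weights and batch-norm running statistics
    of the epoch with the highest validation accuracy (earliest on ties).
    """
    if train.n_trials == 0 or valid.n_trials == 0:
        raise ValueError("train and validation partitions must be non-empty")
    rng = np.random.default_rng(config.seed)
    dtype = net.params[0].dtype
    x_tr, y_tr = _as_input(train, dtype), train.labels
    x_va, y_va = _as_input(valid, dtype), valid.labels
    opt = nn.Adam(net.params, net.grads, lr=config.learning_rate)
    rows = []
    best = (-np.inf, 0, None)
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = net.forward(x_tr[idx], train=True, rng=rng)
            loss, grad = nn.cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            net.backward(grad)
            opt.step()
            losses.append(loss)
        acc = _accuracy(net, x_va, y_va)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "valid_accuracy": acc})
        if acc > best[0]:
            best = (acc, epoch, net.state())
    net.load_state(best[2])
    return TrainedModel(
        name=name, net=net, config=config, history=pd.DataFrame(rows), best_epoch=best[1]
    )


def predict(model: TrainedModel, trials: TrialSet):
    """Labels and class probabilities for a TrialSet (dropout disabled)."""
    x = _as_input(trials, model.net.params[0].dtype)
    probs = []
    for i in range(0, len(x), 256):
        probs.append(nn.softmax(model.net.forward(x[i : i + 256], train=False)))
    probs = np.vstack(probs)
    return np.argmax(probs, axis=1), probs


class _ConvNetEstimator:
    """fit/predict wrapper matching the classical decoders' surface."""

    builder = None
    name = "convnet"

    def __init__(self, epochs: int = 120, batch_size: int = 16, learning_rate: float = 1e-3,
                 dropout: float = 0.5):
        self.epochs, self.batch_size = epochs, batch_size
        self.learning_rate, self.dropout = learning_rate, dropout

    def fit(self, trials: TrialSet, valid: TrialSet | None = None, seed: int = 0):
        if valid is None:
            valid = trials
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            dropout=self.dropout,
            seed=seed,
        )
        net = type(self).builder(
            n_channels=trials.n_channels,
            n_samples=trials.n_samples,
            n_classes=len(trials.class_names),
            dropout=self.dropout,
            seed=seed,
        )
        self.model_ = train_model(net, trials, valid, cfg, name=self.name)
        return self

    def predict(self, trials: TrialSet) -> np.ndarray:
        return predict(self.model_, trials)[0]


class ShallowNet(_ConvNetEstimator):
    builder = staticmethod(build_shallownet)
    name = "ShallowNet"


class EEGNet(_ConvNetEstimator):
    builder = staticmethod(build_eegnet)
    name = "EEGNet"
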