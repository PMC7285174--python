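"""Training protocol: Adam with per-epoch learning-rate decay, binary
cross-entropy loss, fixed epoch budget with early stopping, and
best-accuracy checkpointing.

Defaults follow the reference protocol: 400 epochs, early stop after 150
epochs without improvement, batch size 256, Adam (LR = 0.001, beta1 = 0.9,
beta2 = 0.999) with decay DR = LR / epochs applied as
``LR_t = LR / (1 + DR * t)`` per epoch, uniform-random kernel
initialization, and the model with maximal monitored accuracy saved.
Accuracy = (TP + TN) / total at threshold 0.5; on the balanced training set
it tracks balanced accuracy closely.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dataset import DatasetSplit, make_batches
from .model import (HPConfig, ModelParams, backward, forward, forward_train,
                    init_params, layer_shapes)

_EPS = 1e-7


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy with machine-safe probability clipping."""
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


@dataclasses.dataclass
class TrainSettings:
    epochs: int = 400
    patience: int = 150
    batch_size: int = 256
    lr: float = 0.001
    decay: float | None = None        # None -> lr / epochs
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    monitor: str = "train"            # "train" or "validation"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not (0 <= self.patience < self.epochs):
            raise ValueError("patience must satisfy 0 <= patience < epochs")

    def resolved_decay(self) -> float:
        return self.lr / self.epochs if self.decay is None else self.decay


@dataclasses.dataclass
class TrainResult:
    best_params: ModelParams
    history: pd.DataFrame            # epoch, loss, accuracy, lr
    best_epoch: int                  # 1-based
    best_accuracy: float
    epochs_trained: int
    stopped_early: bool


class _Adam:
    def __init__(self, arrays: list[np.ndarray], beta1: float, beta2: float):
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.b1, self.b2 = beta1, beta2
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            a -= lr * (m / c1) / (np.sqrt(v / c2) + 1e-8)


def accuracy_at_half(config: HPConfig, params: ModelParams, split: DatasetSplit) -> float:
    """(TP + TN) / total at probability threshold 0.5.

    Windows are cast to the parameter dtype first, so the recorded value is
    bit-reproducible when a stored checkpoint is re-evaluated.
    """
    x = split.X.astype(params.conv_w[0].dtype, copy=False)
    p = forward(config, params, x)
    return float(np.mean((p >= 0.5) == (split.y >= 0.5)))


def train_model(
    config: HPConfig,
    train_split: DatasetSplit,
    settings: TrainSettings,
    monitor_split: DatasetSplit | None = None,
) -> TrainResult:
    """Train one network; checkpoint the epoch with maximal monitored accuracy.

    The monitored set is the (balanced) training data by default; pass
    ``monitor_split`` with ``settings.monitor == "validation"`` to monitor an
    internal split instead.  Early stopping triggers once more than
    ``patience`` epochs pass without improvement.  Deterministic given
    ``settings.seed`` (single-threaded).
    """
    if not layer_shapes(config).feasible:
        raise ValueError("infeasible configuration for this input length")
    if len(train_split.y) == 0:
        raise ValueError("empty training split")
    if train_split.X.shape[1] != config.input_len:
        raise ValueError("training window length does not match config.input_len")

    # training arithmetic runs in float32 (the customary network precision);
    # the same seed therefore produces the same run on any platform
    train_split = dataclasses.replace(
        train_split,
        X=train_split.X.astype(np.float32),
        y=train_split.y.astype(np.float32),
    )
    monitored = train_split if settings.monitor == "train" else monitor_split
    if monitored is None:
        raise ValueError("monitor='validation' requires monitor_split")

    params = init_params(config, seed=settings.seed, dtype=np.float32)
    opt = _Adam(params.flat(), settings.beta1, settings.beta2)
    drop_rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 1]))
    decay = settings.resolved_decay()

    workspace: dict = {}  # reusable scratch buffers across batches
    rows = []
    best_acc = -np.inf
    best_params = params.copy()
    best_epoch = 0
    since_best = 0
    stopped_early = False
    epochs_trained = 0

    for epoch in range(1, settings.epochs + 1):
        lr_e = settings.lr / (1.0 + decay * (epoch - 1))
        # fresh shuffle each epoch from an epoch-derived seed
        shuffle_seed = int(np.random.SeedSequence([settings.seed, 2, epoch]).generate_state(1)[0] % (2**31))
        losses = []
        for xb, yb in make_batches(train_split, settings.batch_size, seed=shuffle_seed):
            p, cache = forward_train(config, params, xb, drop_rng, ws=workspace)
            losses.append(bce_loss(p, yb) * len(yb))
            grads = backward(config, params, cache, yb, ws=workspace)
            opt.step(params.flat(), grads.flat(), lr_e)
        epoch_loss = float(np.sum(losses) / len(train_split.y))
        acc = accuracy_at_half(config, params, monitored)
        rows.append({"epoch": epoch, "loss": epoch_loss, "accuracy": acc, "lr": lr_e})
        epochs_trained = epoch
        if acc > best_acc:
            best_acc = acc
            best_params = params.copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > settings.patience:
                stopped_early = True
                break

    return TrainResult(
        best_params=best_params,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_accuracy=float(best_acc),
        epochs_trained=epochs_trained,
        stopped_early=stopped_early,
    )
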