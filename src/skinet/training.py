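"""Training loops for the Bayesian segmenter and classifier.

Both models train with Adam at learning rate 1e-3 on cross-entropy:
pixel-wise binary cross-entropy against the mask for segmentation, and
categorical cross-entropy (the multi-class extension of the binary form)
against one-hot labels for classification. Dropout is always active in
train mode; the full loop — data order, weight initialization and dropout
masks — is deterministic given the seeds.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn import core
from .nn.core import Tensor
from .nets import _to_nchw, save_checkpoint
from .synthetic import LesionSample


class DataError(ValueError):
    """A sample is unusable for the requested task."""


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 10
    seed: int = 0
    checkpoint_dir: str | Path | None = None
    validation_fraction: float = 0.2

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_segmenter(model: nn.Module, dataset: list[LesionSample],
                    config: TrainConfig) -> tuple[nn.Module, list[float]]:
    """Minimize pixel-wise BCE between the sigmoid map and the mask."""
    for s in dataset:
        if s.mask is None:
            raise DataError(f"sample {s.sample_id!r} has no mask")
    images = np.stack([_to_nchw(s.image)[0] for s in dataset])
    masks = np.stack([s.mask.astype(np.float64) for s in dataset])
    rng = np.random.default_rng(config.seed)
    model.set_rng(np.random.default_rng(rng.integers(2 ** 31)))
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = []
    model.train_mode()
    for epoch in range(config.epochs):
        losses = []
        for idx in _epoch_batches(len(dataset), config.batch_size, rng):
            x = Tensor(images[idx])
            y = masks[idx][:, None]
            p = model(x)
            logp = core.log(p)
            log1mp = core.log(Tensor(1.0) - p)
            loss = -core.mean(Tensor(y) * logp + Tensor(1.0 - y) * log1mp)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if config.checkpoint_dir is not None:
            save_checkpoint(model, Path(config.checkpoint_dir) / f"seg_epoch{epoch:03d}.npz")
    model.eval_mode()
    return model, history


def train_classifier(model: nn.Module, dataset: list[LesionSample],
                     config: TrainConfig) -> tuple[nn.Module, list[float]]:
    """Minimize categorical cross-entropy over the class labels."""
    n_classes = model.spec.n_classes
    for s in dataset:
        if s.label is None or not 0 <= s.label < n_classes:
            raise DataError(f"sample {s.sample_id!r} has invalid label {s.label}")
    images = np.stack([_to_nchw(s.image)[0] for s in dataset])
    labels = np.array([s.label for s in dataset])
    rng = np.random.default_rng(config.seed)
    model.set_rng(np.random.default_rng(rng.integers(2 ** 31)))
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = []
    model.train_mode()
    for epoch in range(config.epochs):
        losses = []
        for idx in _epoch_batches(len(dataset), config.batch_size, rng):
            x = Tensor(images[idx])
            logits = model(x)
            logp = core.log_softmax(logits, axis=1)
            picked = core.select(logp, (np.arange(len(idx)), labels[idx]))
            loss = -core.mean(picked)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if config.checkpoint_dir is not None:
            save_checkpoint(model, Path(config.checkpoint_dir) / f"cls_epoch{epoch:03d}.npz")
    model.eval_mode()
    return model, history


def train_validation_split(dataset: list[LesionSample], fraction: float = 0.2,
                           seed: int = 0) -> tuple[list[LesionSample], list[LesionSample]]:
    """Seeded shuffle then an 80/20-style split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_val = int(round(fraction * len(dataset)))
    val_idx = set(order[:n_val].tolist())
    train = [dataset[i] for i in range(len(dataset)) if i not in val_idx]
    val = [dataset[i] for i in range(len(dataset)) if i in val_idx]
    return train, val


def save_history(history: list[float], path: str | Path) -> None:
    pd.DataFrame({"epoch": range(len(history)), "loss": history}).to_csv(
        path, index=False)
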