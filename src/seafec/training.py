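"""Desk-scale smoke training.

A deliberately small training loop whose purpose is to prove that every
backbone variant optimises end to end on the synthetic fixtures — not
to reach benchmark accuracy.  The optimiser follows the reference
classification recipe: Adam, initial learning rate 1e-3, batch size 32,
fixed seed 42.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from . import tensor as T
from .metrics import MetricsReport, classification_metrics
from .tensor import Tensor

__all__ = ["Adam", "TrainingDiverged", "TrainingHistory", "smoke_train", "images_to_batch"]


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


class Adam:
    """Adam optimiser (decoupled from the module system; operates on the
    parameter tensors directly)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrainingHistory:
    losses: list[float] = field(default_factory=list)        # mean loss per epoch
    accuracies: list[float] = field(default_factory=list)    # train accuracy per epoch
    final_metrics: MetricsReport | None = None

    @property
    def epochs(self) -> int:
        return len(self.losses)

    def to_csv(self, path: str | Path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "loss", "train_accuracy"])
            for i, (l, a) in enumerate(zip(self.losses, self.accuracies), 1):
                w.writerow([i, l, a])


def images_to_batch(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8 -> (N, 3, H, W) float32, standardised to ~[-2, 2]."""
    x = images.astype(np.float32) / 255.0
    return np.ascontiguousarray(((x - 0.5) / 0.25).transpose(0, 3, 1, 2))


def smoke_train(
    model: nn.Module,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int = 30,
    seed: int = 42,
    batch_size: int = 32,
    lr: float = 1e-3,
    eval_data: tuple[np.ndarray, np.ndarray] | None = None,
    stop_at_accuracy: float | None = None,
) -> TrainingHistory:
    """Train a classifier on an in-memory fixture; deterministic under seed.

    Records per-epoch mean loss and running train accuracy (predictions
    of the training-mode forward passes).  Stops early once the train
    accuracy reaches ``stop_at_accuracy``.  Non-finite loss raises
    :class:`TrainingDiverged` with the epoch index.  If ``eval_data`` is
    given, final held-out classification metrics are computed in
    inference mode.
    """
    x_all = images_to_batch(images) if images.ndim == 4 and images.shape[-1] == 3 else images
    y_all = np.asarray(labels, dtype=np.int64)
    n = len(y_all)
    n_classes = int(y_all.max()) + 1
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    history = TrainingHistory()
    model.train()
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = Tensor(x_all[idx])
            yb = y_all[idx]
            opt.zero_grad()
            out = model(xb)
            loss = T.cross_entropy(out, yb)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(epoch)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((out.data.argmax(axis=1) == yb).sum())
        history.losses.append(float(np.mean(losses)))
        history.accuracies.append(correct / n)
        if stop_at_accuracy is not None and history.accuracies[-1] >= stop_at_accuracy:
            break
    if eval_data is not None:
        ex, ey = eval_data
        ex = images_to_batch(ex) if ex.ndim == 4 and ex.shape[-1] == 3 else ex
        model.eval()
        with T.no_grad():
            preds = []
            for start in range(0, len(ey), batch_size):
                out = model(Tensor(ex[start : start + batch_size]))
                preds.append(out.data.argmax(axis=1))
        history.final_metrics = classification_metrics(
            ey, np.concatenate(preds), n_classes
        )
    return history
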