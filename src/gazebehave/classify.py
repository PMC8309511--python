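"""Stare/move window classifiers: three small convolutional architectures.

The three nets mirror a deliberately simple design ladder:

``cnn3``
    3 convolutional layers, 1 max-pool, 2 fully connected layers, ReLU.
``alexnet_like``
    5 convolutional layers, 3 max-pools, 3 fully connected layers, ReLU —
    an AlexNet-style stack scaled down to 64x64 grayscale input.
``lenet_like``
    2 convolutional layers, 2 max-pools, 3 fully connected layers, sigmoid
    activations (LeNet-5 style).

Unstated hyperparameters are fixed here: 3x3/5x5 kernels, modest channel
widths, cross-entropy loss, Adam at 1e-3, batch 64, inputs scaled to
[0, 1].  Training is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .core import EventSegment, GazeRecording, segments_from_labels
from .windows import CLASSES, WindowDataset, WindowSpec, extract_window

__all__ = [
    "ArchitectureSpec",
    "ARCHITECTURES",
    "Confusion",
    "TrainReport",
    "build_model",
    "train",
    "accuracy",
    "confusion_from_predictions",
    "cross_entropy",
    "classify_recording",
    "merge_short_runs",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer-count contract of one of the three architectures."""

    name: str
    n_conv: int
    n_pool: int
    n_fc: int
    activation: str  # relu | sigmoid


ARCHITECTURES = {
    "cnn3": ArchitectureSpec("cnn3", 3, 1, 2, "relu"),
    "alexnet_like": ArchitectureSpec("alexnet_like", 5, 3, 3, "relu"),
    "lenet_like": ArchitectureSpec("lenet_like", 2, 2, 3, "sigmoid"),
}


def build_model(name: str, resolution: int = 64, seed: int = 0) -> nn.Sequential:
    """Instantiate one of the three architectures for a square input."""
    if name not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {name!r}; choose {sorted(ARCHITECTURES)}")
    rng = np.random.default_rng(seed)
    if resolution % 8 != 0 or resolution < 16:
        raise ValueError("resolution must be a multiple of 8 and >= 16")
    r = resolution
    if name == "cnn3":
        # conv(s2) conv(s2) conv pool : r -> r/2 -> r/4 -> pool r/8
        feat = 16 * (r // 8) * (r // 8)
        return nn.Sequential(
            [
                nn.Conv2D(1, 8, 3, stride=2, pad=1, rng=rng),
                nn.ReLU(),
                nn.Conv2D(8, 12, 3, stride=2, pad=1, rng=rng),
                nn.ReLU(),
                nn.Conv2D(12, 16, 3, stride=1, pad=1, rng=rng),
                nn.ReLU(),
                nn.MaxPool2D(),
                nn.Flatten(),
                nn.Dense(feat, 64, rng=rng),
                nn.ReLU(),
                nn.Dense(64, 2, rng=rng),
            ]
        )
    if name == "alexnet_like":
        feat = 16 * (r // 16) * (r // 16)
        return nn.Sequential(
            [
                nn.Conv2D(1, 8, 5, stride=2, pad=2, rng=rng),
                nn.ReLU(),
                nn.MaxPool2D(),
                nn.Conv2D(8, 16, 3, stride=1, pad=1, rng=rng),
                nn.ReLU(),
                nn.MaxPool2D(),
                nn.Conv2D(16, 24, 3, stride=1, pad=1, rng=rng),
                nn.ReLU(),
                nn.Conv2D(24, 24, 3, stride=1, pad=1, rng=rng),
                nn.ReLU(),
                nn.Conv2D(24, 16, 3, stride=1, pad=1, rng=rng),
                nn.ReLU(),
                nn.MaxPool2D(),
                nn.Flatten(),
                nn.Dense(feat, 64, rng=rng),
                nn.ReLU(),
                nn.Dense(64, 32, rng=rng),
                nn.ReLU(),
                nn.Dense(32, 2, rng=rng),
            ]
        )
    # lenet_like: conv(s2) pool conv pool; sigmoid activations throughout
    side = ((r // 4) - 4) // 2  # 5x5 valid conv then pool
    feat = 16 * side * side
    return nn.Sequential(
        [
            nn.Conv2D(1, 6, 5, stride=2, pad=2, rng=rng),
            nn.Sigmoid(),
            nn.MaxPool2D(),
            nn.Conv2D(6, 16, 5, stride=1, pad=0, rng=rng),
            nn.Sigmoid(),
            nn.MaxPool2D(),
            nn.Flatten(),
            nn.Dense(feat, 120, rng=rng),
            nn.Sigmoid(),
            nn.Dense(120, 84, rng=rng),
            nn.Sigmoid(),
            nn.Dense(84, 2, rng=rng),
        ]
    )


@dataclass
class TrainReport:
    """Per-epoch accuracy and loss on train and validation sets."""

    history: pd.DataFrame  # epoch, train_acc, train_loss, val_acc, val_loss
    epochs: int
    seed: int

    @property
    def final_val_accuracy(self) -> float:
        return float(self.history["val_acc"].iloc[-1])

    def to_csv(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


def _as_batch_input(images: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(images[:, None, :, :].astype(np.float32))


def _evaluate(model: nn.Sequential, x: np.ndarray, y: np.ndarray,
              batch: int = 256) -> tuple[float, float]:
    losses = []
    correct = 0
    for lo in range(0, len(x), batch):
        logits = model.forward(x[lo : lo + batch])
        loss, _ = nn.softmax_cross_entropy(logits, y[lo : lo + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[lo : lo + batch]).sum())
    return correct / len(y), float(np.sum(losses) / len(y))


def train(
    arch: str | ArchitectureSpec,
    train_set: WindowDataset,
    val_set: WindowDataset,
    epochs: int = 6,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 64,
) -> tuple[nn.Sequential, TrainReport]:
    """Train one architecture on a balanced window dataset.

    Deterministic for a fixed seed: weight init and epoch shuffles all draw
    from one seeded generator.
    """
    name = arch.name if isinstance(arch, ArchitectureSpec) else arch
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty dataset")
    res = train_set.images.shape[1]
    model = build_model(name, resolution=res, seed=seed)
    model.arch_name = name
    model.resolution = res
    model.seed = seed
    rng = np.random.default_rng(seed + 1)
    opt = nn.Adam(model.params, lr=lr)
    x_train = _as_batch_input(train_set.images)
    y_train = train_set.labels
    x_val = _as_batch_input(val_set.images)
    y_val = val_set.labels
    rows = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(x_train))
        ep_loss = 0.0
        ep_correct = 0
        for lo in range(0, len(order), batch_size):
            idx = order[lo : lo + batch_size]
            logits = model.forward(x_train[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            opt.step(model.grads)
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
        val_acc, val_loss = _evaluate(model, x_val, y_val)
        rows.append(
            {
                "epoch": epoch,
                "train_acc": ep_correct / len(order),
                "train_loss": ep_loss / len(order),
                "val_acc": val_acc,
                "val_loss": val_loss,
            }
        )
    report = TrainReport(pd.DataFrame(rows), epochs=epochs, seed=seed)
    return model, report


# ---------------------------------------------------------------------------
# Metrics on 2-class predictions (positive class = stare)
# ---------------------------------------------------------------------------


@dataclass
class Confusion:
    """2-class confusion counts; the positive class is *stare*."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_from_predictions(pred: np.ndarray, truth: np.ndarray) -> Confusion:
    """Build confusion counts from integer class ids (stare = positive)."""
    stare = CLASSES.index("stare")
    p = np.asarray(pred) == stare
    y = np.asarray(truth) == stare
    return Confusion(
        TP=int(np.sum(p & y)),
        FP=int(np.sum(p & ~y)),
        FN=int(np.sum(~p & y)),
        TN=int(np.sum(~p & ~y)),
    )


def accuracy(c: Confusion) -> float:
    """Classification accuracy (TP + TN) / total."""
    if c.total == 0:
        raise ValueError("empty confusion")
    return (c.TP + c.TN) / c.total


def cross_entropy(P: np.ndarray, Q: np.ndarray, eps: float = 1e-12) -> float:
    """H(P, Q) = -sum P(x) log Q(x) for one distribution pair (natural log).

    Q is clipped by ``eps`` where P > 0 so one-hot targets with a vanishing
    prediction stay finite.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    if np.any(P < 0) or np.any(Q < 0):
        raise ValueError("distributions must be non-negative")
    mask = P > 0
    return float(-np.sum(P[mask] * np.log(np.clip(Q[mask], eps, None))))


# ---------------------------------------------------------------------------
# Recording-level behaviour segmentation
# ---------------------------------------------------------------------------


def merge_short_runs(labels: list[str], min_run: int) -> list[str]:
    """Merge runs shorter than ``min_run`` into the neighbouring majority
    label; ties resolve toward stare.  ``min_run=1`` is the identity."""
    if min_run <= 1:
        return list(labels)
    labels = list(labels)
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i - 1, labels[start]))
                start = i
        if len(runs) <= 1:
            break
        for k, (a, b, lab) in enumerate(runs):
            if b - a + 1 >= min_run:
                continue
            prev_len = runs[k - 1][1] - runs[k - 1][0] + 1 if k > 0 else -1
            next_len = runs[k + 1][1] - runs[k + 1][0] + 1 if k + 1 < len(runs) else -1
            if prev_len < 0 and next_len < 0:
                continue
            if prev_len > next_len:
                new = runs[k - 1][2]
            elif next_len > prev_len:
                new = runs[k + 1][2]
            else:  # tie -> stare
                cands = {runs[k - 1][2], runs[k + 1][2]}
                new = "stare" if "stare" in cands else runs[k - 1][2]
            if new != lab:
                labels[a : b + 1] = [new] * (b - a + 1)
                changed = True
                break
    return labels


def classify_recording(
    model,
    rec: GazeRecording,
    spec: WindowSpec,
    min_run: int = 2,
    batch: int = 256,
) -> list[EventSegment]:
    """Predict stare/move per sample via each sample's window, merge runs
    shorter than ``min_run`` into the neighbouring majority label, and emit
    maximal runs as segments partitioning the recording."""
    n = len(rec)
    images = np.zeros((n, spec.resolution_px, spec.resolution_px), dtype=np.float32)
    for i in range(n):
        images[i] = extract_window(rec, i, spec).raster
    pred = model.predict(_as_batch_input(images), batch=batch)
    labels = [CLASSES[k] for k in pred]
    labels = merge_short_runs(labels, min_run)
    return segments_from_labels(rec, labels)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_model(model: nn.Sequential, path: str | Path) -> None:
    """Single-file checkpoint embedding architecture name, input size, seed."""
    arrays = {f"p{k}": p for k, p in enumerate(model.params)}
    np.savez(
        path,
        arch=np.array(getattr(model, "arch_name", "cnn3")),
        resolution=np.array(getattr(model, "resolution", 64)),
        seed=np.array(getattr(model, "seed", 0)),
        **arrays,
    )


def load_model(path: str | Path) -> nn.Sequential:
    data = np.load(path, allow_pickle=False)
    name = str(data["arch"])
    res = int(data["resolution"])
    seed = int(data["seed"])
    model = build_model(name, resolution=res, seed=seed)
    model.arch_name = name
    model.resolution = res
    model.seed = seed
    state = [data[f"p{k}"] for k in range(len(model.params))]
    model.load_state(state)
    return model
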