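"""Behaviour-based gaze data processing: sliding-window rasterization.

A square window (default 32 x 32 degrees, chosen so that both the foveal
1–2 degree extent and a 10–30 deg/s pursuit arc fit inside) is centred on
each gaze sample in turn.  The current sample and its ``history_n``
predecessors that fall inside the window are rendered as grayscale dots on
a black background, with opacity decreasing with age so the raster encodes
the recent movement direction.  *Stare* behaviour (fixation or smooth
pursuit) produces compact dot clusters or short arcs; *move* behaviour
(saccades, PSO) produces gapped, scattered dots.  The labelled rasters are
the training data for the stare/move classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .core import GazeRecording

__all__ = [
    "WindowSpec",
    "BehaviorWindow",
    "WindowDataset",
    "extract_window",
    "extract_windows",
    "label_from_events",
    "behavior_label",
    "build_dataset",
    "load_dataset",
    "STARE_MAP",
]

#: event-label -> behaviour-label mapping: fixation and smooth pursuit are
#: actions holding the target on the fovea (stare); saccade and PSO are
#: repositionings (move).  Anything else is unlabeled and excluded.
STARE_MAP = {
    "fixation": "stare",
    "smooth_pursuit": "stare",
    "saccade": "move",
    "pso": "move",
}

CLASSES = ("move", "stare")  # index = integer class id; stare is positive


def linear_fade(age: int, history_n: int) -> float:
    """Default opacity profile: linear in age, fade(0) = 1."""
    return (history_n + 1 - age) / (history_n + 1)


@dataclass
class WindowSpec:
    """Geometry of the behaviour window raster.

    ``fade`` maps dot age (0 = the current sample) to opacity in (0, 1] and
    must be strictly decreasing with fade(0) = 1; default is linear.
    """

    extent_deg: float = 32.0
    resolution_px: int = 64
    history_n: int = 8
    dot_radius_px: int = 1
    fade: Callable[[int, int], float] = linear_fade

    def __post_init__(self) -> None:
        if self.extent_deg <= 0:
            raise ValueError("extent_deg must be > 0")
        if self.resolution_px < 8:
            raise ValueError("resolution_px must be >= 8")
        if self.history_n < 0:
            raise ValueError("history_n must be >= 0")
        if abs(self.fade(0, self.history_n) - 1.0) > 1e-9:
            raise ValueError("fade(0) must be 1")
        vals = [self.fade(a, self.history_n) for a in range(self.history_n + 1)]
        if any(b >= a for a, b in zip(vals, vals[1:])):
            raise ValueError("fade must be strictly decreasing in age")
        if any(v <= 0 for v in vals):
            raise ValueError("fade must stay positive over the history")


@dataclass
class BehaviorWindow:
    """One rasterized window: grayscale intensities in [0, 1], black background."""

    raster: np.ndarray  # (res, res) float32
    anchor_index: int
    label: str = "unlabeled"  # stare / move / unlabeled


def _deg_to_px(offset_deg: float, extent: float, res: int) -> int:
    """Affine window map: -extent/2 -> 0, +extent/2 -> res (floor to cell)."""
    return int(np.floor((offset_deg + extent / 2.0) / extent * res))


def extract_window(rec: GazeRecording, i: int, spec: WindowSpec) -> BehaviorWindow:
    """Render the window anchored at sample ``i``.

    Samples i-history_n..i inside the window are drawn oldest-first as dots
    whose opacity follows ``fade`` by age; overlapping dots combine by
    maximum so the newest dot stays on top.  The anchor renders exactly at
    the raster centre.
    """
    if rec.unit != "degrees":
        raise ValueError("window extraction requires a recording in degrees")
    if not 0 <= i < len(rec):
        raise IndexError("anchor index out of range")
    res = spec.resolution_px
    raster = np.zeros((res, res), dtype=np.float32)
    x0, y0 = rec.x[i], rec.y[i]
    r = spec.dot_radius_px
    for age in range(spec.history_n, -1, -1):
        j = i - age
        if j < 0:
            continue
        px = _deg_to_px(rec.x[j] - x0, spec.extent_deg, res)
        py = _deg_to_px(rec.y[j] - y0, spec.extent_deg, res)
        if not (0 <= px < res and 0 <= py < res):
            continue
        opacity = np.float32(spec.fade(age, spec.history_n))
        lo_y, hi_y = max(py - r + 1, 0), min(py + r, res)
        lo_x, hi_x = max(px - r + 1, 0), min(px + r, res)
        patch = raster[lo_y:hi_y, lo_x:hi_x]
        np.maximum(patch, opacity, out=patch)
    return BehaviorWindow(raster=raster, anchor_index=i)


def extract_windows(
    rec: GazeRecording, spec: WindowSpec, indices: Sequence[int] | None = None
) -> list[BehaviorWindow]:
    """One window per gaze sample (or per requested anchor), in time order."""
    if indices is None:
        indices = range(len(rec))
    return [extract_window(rec, int(i), spec) for i in indices]


def behavior_label(event_label: str) -> str:
    return STARE_MAP.get(event_label, "unlabeled")


def label_from_events(
    windows: Sequence[BehaviorWindow], truth: Sequence[str]
) -> list[BehaviorWindow]:
    """Attach stare/move labels from per-sample truth labels.

    fixation/smooth_pursuit -> stare; saccade/pso -> move; anything else ->
    unlabeled (excluded from datasets).  Raises if an anchor has no truth.
    """
    truth = list(truth)
    for w in windows:
        if w.anchor_index >= len(truth):
            raise ValueError(f"no truth label for anchor {w.anchor_index}")
        w.label = behavior_label(truth[w.anchor_index])
    return list(windows)


@dataclass
class WindowDataset:
    """In-memory labelled window set (images in [0, 1], labels as class ids)."""

    images: np.ndarray  # (N, res, res) float32
    labels: np.ndarray  # (N,) int, index into CLASSES
    manifest: pd.DataFrame  # file, recording_id, anchor_index, label

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == k)) for k, c in enumerate(CLASSES)}

    def save(self, out_dir: str | Path, split_name: str = "train") -> None:
        """Serialize as 8-bit grayscale PNGs under <out>/<split>/<class>/."""
        out_dir = Path(out_dir)
        files = []
        for n in range(len(self)):
            cls = CLASSES[self.labels[n]]
            d = out_dir / split_name / cls
            d.mkdir(parents=True, exist_ok=True)
            fname = d / f"{split_name}_{n:06d}.png"
            img = (np.clip(self.images[n], 0, 1) * 255).astype(np.uint8)
            Image.fromarray(img, mode="L").save(fname)
            files.append(str(fname.relative_to(out_dir)))
        manifest = self.manifest.copy()
        manifest["file"] = files
        manifest.to_csv(out_dir / f"manifest_{split_name}.csv", index=False)


def build_dataset(
    recordings: Sequence[tuple[GazeRecording, Sequence[str]]],
    spec: WindowSpec,
    n_per_class: int,
    split: float = 0.5,
    seed: int = 0,
) -> tuple[WindowDataset, WindowDataset]:
    """Build balanced train/validation window sets from labelled recordings.

    ``n_per_class`` windows are drawn per class over all recordings (error
    reporting the shortfall when a class has too few labelled anchors),
    then split ``split`` : 1-split into train and validation per class.
    Deterministic for a given seed.
    """
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    rng = np.random.default_rng(seed)
    candidates: dict[str, list[tuple[int, int]]] = {c: [] for c in CLASSES}
    for rid, (rec, truth) in enumerate(recordings):
        truth = list(truth)
        if len(truth) != len(rec):
            raise ValueError(f"recording {rid}: truth must cover every sample")
        for i, lab in enumerate(truth):
            b = behavior_label(lab)
            if b in candidates:
                candidates[b].append((rid, i))
    for c in CLASSES:
        if len(candidates[c]) < n_per_class:
            raise ValueError(
                f"insufficient {c!r} windows: need {n_per_class}, "
                f"have {len(candidates[c])} (short {n_per_class - len(candidates[c])})"
            )
    n_train = int(round(n_per_class * split))
    picks = {}
    for c in CLASSES:
        pool = candidates[c]
        idx = rng.permutation(len(pool))[:n_per_class]
        picks[c] = [pool[k] for k in idx]

    def render(items: list[tuple[int, int, str]]) -> WindowDataset:
        images = np.zeros(
            (len(items), spec.resolution_px, spec.resolution_px), dtype=np.float32
        )
        labels = np.zeros(len(items), dtype=np.int64)
        rows = []
        for n, (rid, i, c) in enumerate(items):
            rec, _ = recordings[rid]
            images[n] = extract_window(rec, i, spec).raster
            labels[n] = CLASSES.index(c)
            rows.append({"recording_id": rid, "anchor_index": i, "label": c})
        return WindowDataset(images, labels, pd.DataFrame(rows))

    train_items: list[tuple[int, int, str]] = []
    val_items: list[tuple[int, int, str]] = []
    for c in CLASSES:
        sel = picks[c]
        train_items += [(rid, i, c) for rid, i in sel[:n_train]]
        val_items += [(rid, i, c) for rid, i in sel[n_train:]]
    # deterministic interleave so batches see both classes
    train_order = rng.permutation(len(train_items))
    val_order = rng.permutation(len(val_items))
    train = render([train_items[k] for k in train_order])
    val = render([val_items[k] for k in val_order])
    return train, val


def load_dataset(out_dir: str | Path, split_name: str = "train") -> WindowDataset:
    """Load a dataset previously written by :meth:`WindowDataset.save`."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / f"manifest_{split_name}.csv")
    images = []
    labels = []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(out_dir / row["file"]), dtype=np.float32) / 255.0
        images.append(img)
        labels.append(CLASSES.index(row["label"]))
    return WindowDataset(np.stack(images), np.asarray(labels, dtype=np.int64), manifest)
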