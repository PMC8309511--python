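"""Classical gaze-parsing algorithms: I-VT, I-DT, DBSCAN-with-IQR, I-VDT.

All detectors consume a degree-unit :class:`~gazebehave.core.GazeRecording`
and return a chronological list of :class:`~gazebehave.core.EventSegment`
that partitions the sample index range with no gaps or overlaps.

I-VT
    One parameter, a velocity threshold v_T (deg/s): samples slower than v_T
    are fixation, the rest saccade.  Deliberately no minimum-duration filter,
    so threshold-boundary "blips" are preserved; use
    :func:`merge_short_segments` to clean them up post hoc.
I-DT
    Window-growth dispersion algorithm (Salvucci & Goldberg formulation):
    a window is initialized to cover the duration threshold, grown while
    dispersion (x-range + y-range) stays within D_T, and emitted as fixation.
DBSCAN with IQR
    Density clustering on (x, y, weighted time) where eps defaults to the
    third quartile of sample distances from the data centroid.  The auto
    rule suits recordings concentrated around one area; pass an explicit
    ``eps`` (foveal scale, ~1 deg) for multi-target layouts.
I-VDT
    Two stages: a velocity gate removes saccades, then each slow run is
    split into fixation windows (dispersion <= D_T over at least a minimum
    duration) and smooth-pursuit remainders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EventSegment, GazeRecording, sample_velocities, segments_from_labels

__all__ = [
    "DetectorParams",
    "ivt",
    "idt",
    "dbscan_eps_iqr",
    "dbscan_labels",
    "dbscan_iqr",
    "ivdt",
    "merge_short_segments",
    "stare_regions",
    "RECOMMENDED",
]


@dataclass
class DetectorParams:
    """Parameter bundle for the four detectors.

    ``eps`` is optional: when None the DBSCAN radius is computed by the IQR
    rule (:func:`dbscan_eps_iqr`).
    """

    velocity_threshold: float = 30.0  # deg/s (I-VT, I-VDT)
    dispersion_threshold: float = 2.0  # deg (I-DT, I-VDT)
    duration_threshold: float = 100.0  # ms (I-DT)
    min_points: int = 4  # DBSCAN
    eps: float | None = None  # deg; None -> IQR rule
    time_weight: float = 1.0  # DBSCAN third-coordinate weight

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0:
            raise ValueError("velocity_threshold must be > 0")
        if self.dispersion_threshold <= 0:
            raise ValueError("dispersion_threshold must be > 0")
        if self.duration_threshold <= 0:
            raise ValueError("duration_threshold must be > 0")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be > 0 when supplied")


#: parameters that recover the scripted structure of the bundled simulator
#: tasks (multi-target box task and 30 deg/s pursuit task) at 40 Hz
RECOMMENDED = {
    "four_target": {
        "ivt": {"v_T": 30.0},
        "idt": {"D_T": 3.0, "dur_T": 100.0},
        "dbscan": {"min_points": 4, "eps": 1.0, "time_weight": 1.0},
        "ivdt": {"v_T": 30.0, "D_T": 3.0},
    },
    "six_point": {
        "ivt": {"v_T": 45.0},
        "ivdt": {"v_T": 50.0, "D_T": 1.5},
    },
}


def _check_rec(rec: GazeRecording) -> None:
    if rec.unit != "degrees":
        raise ValueError("detectors require a recording in degrees")
    if len(rec) < 2:
        raise ValueError("detectors require at least 2 samples")


# ---------------------------------------------------------------------------
# I-VT
# ---------------------------------------------------------------------------


def ivt(rec: GazeRecording, v_T: float) -> list[EventSegment]:
    """Velocity-threshold identification.

    Each sample with point-to-point velocity < v_T is fixation, otherwise
    saccade; maximal equal-label runs become segments.  The first sample's
    velocity is 0, so the recording can never open with a saccade.
    """
    _check_rec(rec)
    if v_T <= 0:
        raise ValueError("v_T must be > 0")
    v = sample_velocities(rec)
    labels = np.where(v < v_T, "fixation", "saccade")
    return segments_from_labels(rec, labels)


# ---------------------------------------------------------------------------
# I-DT
# ---------------------------------------------------------------------------


def _dispersion(x: np.ndarray, y: np.ndarray, i: int, j: int) -> float:
    xs = x[i : j + 1]
    ys = y[i : j + 1]
    return float((xs.max() - xs.min()) + (ys.max() - ys.min()))


def idt(rec: GazeRecording, D_T: float, dur_T: float) -> list[EventSegment]:
    """Dispersion-threshold identification (window growth).

    Initialize a window covering ``dur_T`` ms; if its dispersion
    (x-range + y-range) is <= ``D_T`` grow it until dispersion would exceed
    the threshold and emit the window as a fixation, otherwise slide one
    sample forward.  Samples outside fixations become saccade runs.
    """
    _check_rec(rec)
    if D_T <= 0 or dur_T <= 0:
        raise ValueError("D_T and dur_T must be > 0")
    n = len(rec)
    t, x, y = rec.t, rec.x, rec.y
    windows: list[tuple[int, int]] = []
    i = 0
    while i < n:
        # smallest j with window duration >= dur_T
        j = int(np.searchsorted(t, t[i] + dur_T, side="left"))
        if j >= n:
            break
        if _dispersion(x, y, i, j) <= D_T:
            while j + 1 < n and _dispersion(x, y, i, j + 1) <= D_T:
                j += 1
            windows.append((i, j))
            i = j + 1
        else:
            i += 1
    # each grown window is one fixation even when windows touch, so every
    # emitted fixation individually satisfies both thresholds
    segments: list[EventSegment] = []
    pos = 0
    for lo, hi in windows:
        if lo > pos:
            segments.append(EventSegment.from_span(rec, "saccade", pos, lo - 1))
        segments.append(EventSegment.from_span(rec, "fixation", lo, hi))
        pos = hi + 1
    if pos < n:
        segments.append(EventSegment.from_span(rec, "saccade", pos, n - 1))
    return segments


# ---------------------------------------------------------------------------
# DBSCAN with IQR
# ---------------------------------------------------------------------------


def dbscan_eps_iqr(rec: GazeRecording) -> float:
    """Automatic DBSCAN radius: Q3 of distances from samples to their centroid.

    Quartiles use linear interpolation between order statistics.  Returns 0
    for a degenerate recording whose points all coincide; callers must then
    supply an explicit eps.
    """
    if len(rec) < 4:
        raise ValueError("IQR eps rule needs at least 4 samples")
    cx, cy = float(np.mean(rec.x)), float(np.mean(rec.y))
    d = np.hypot(rec.x - cx, rec.y - cy)
    return float(np.percentile(d, 75))


def _dbscan_features(rec: GazeRecording, time_weight: float) -> np.ndarray:
    """Stack (x, y, w * t_scaled) with time min-max scaled to the spatial extent."""
    extent = max(
        float(rec.x.max() - rec.x.min()),
        float(rec.y.max() - rec.y.min()),
    )
    span = float(rec.t[-1] - rec.t[0])
    if span > 0 and extent > 0:
        t_scaled = (rec.t - rec.t[0]) / span * extent
    else:
        t_scaled = np.zeros_like(rec.t)
    return np.column_stack([rec.x, rec.y, time_weight * t_scaled])


def dbscan_labels(
    rec: GazeRecording,
    min_points: int,
    time_weight: float = 1.0,
    eps: float | None = None,
) -> np.ndarray:
    """Cluster assignment of the time-weighted DBSCAN (-1 marks noise).

    A point is core when its eps-ball (the point itself included) contains
    at least ``min_points`` points.  Core points are chained into clusters;
    a non-core point reached by several clusters is assigned to the cluster
    of its lowest-index core neighbour.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    if eps is None:
        eps = dbscan_eps_iqr(rec)
    if eps <= 0:
        raise ValueError(
            "eps is 0 (degenerate recording); supply an explicit eps to dbscan_iqr"
        )
    pts = _dbscan_features(rec, time_weight)
    n = len(pts)
    # pairwise neighbourhood; gaze traces are short enough for the dense form
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    adj = d2 <= eps * eps
    n_neighbors = adj.sum(axis=1)  # includes the point itself
    core = n_neighbors >= min_points
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for start in range(n):
        if not core[start] or labels[start] != -1:
            continue
        # breadth-first expansion over core points
        stack = [start]
        labels[start] = cid
        while stack:
            p = stack.pop()
            for q in np.nonzero(adj[p])[0]:
                if core[q] and labels[q] == -1:
                    labels[q] = cid
                    stack.append(q)
        cid += 1
    # border points: lowest-index core neighbour wins
    for p in range(n):
        if core[p] or not adj[p][core].any():
            continue
        neighbors = np.nonzero(adj[p] & core)[0]
        labels[p] = labels[neighbors[0]]
    return labels


def dbscan_iqr(
    rec: GazeRecording,
    min_points: int,
    time_weight: float = 1.0,
    eps: float | None = None,
) -> list[EventSegment]:
    """DBSCAN-with-IQR fixation identification.

    Each cluster becomes a fixation segment spanning its members' index
    range (clusters reported chronologically by first member); noise
    samples in between become saccade spans.  Overlapping cluster spans are
    resolved chronologically so the output partitions the recording.
    """
    _check_rec(rec)
    cluster = dbscan_labels(rec, min_points, time_weight, eps)
    n = len(rec)
    spans: list[tuple[int, int]] = []
    for cid in range(cluster.max() + 1 if cluster.max() >= 0 else 0):
        idx = np.nonzero(cluster == cid)[0]
        if idx.size:
            spans.append((int(idx[0]), int(idx[-1])))
    spans.sort()
    segments: list[EventSegment] = []
    pos = 0
    for lo, hi in spans:
        lo = max(lo, pos)
        if hi < pos:
            continue  # fully absorbed by an earlier span
        if lo > pos:
            segments.append(EventSegment.from_span(rec, "saccade", pos, lo - 1))
        segments.append(EventSegment.from_span(rec, "fixation", lo, hi))
        pos = hi + 1
    if pos < n:
        segments.append(EventSegment.from_span(rec, "saccade", pos, n - 1))
    return segments


# ---------------------------------------------------------------------------
# I-VDT
# ---------------------------------------------------------------------------


def ivdt(
    rec: GazeRecording,
    v_T: float,
    D_T: float,
    min_fix_dur_ms: float = 100.0,
) -> list[EventSegment]:
    """Velocity + dispersion two-stage classification.

    Stage 1: samples with velocity >= v_T are saccade.  Stage 2: within each
    slow run, a growing sub-window (initialized to cover ``min_fix_dur_ms``,
    same growth rule as I-DT) claims fixation stretches with dispersion
    <= D_T; samples that cannot open such a window are smooth pursuit.
    """
    _check_rec(rec)
    if v_T <= 0 or D_T <= 0:
        raise ValueError("v_T and D_T must be > 0")
    v = sample_velocities(rec)
    n = len(rec)
    t, x, y = rec.t, rec.x, rec.y
    labels = np.empty(n, dtype=object)
    labels[v >= v_T] = "saccade"
    slow = v < v_T
    # iterate over maximal slow runs
    i = 0
    while i < n:
        if not slow[i]:
            i += 1
            continue
        a = i
        while i < n and slow[i]:
            i += 1
        b = i - 1
        _classify_slow_run(t, x, y, labels, a, b, D_T, min_fix_dur_ms)
    return segments_from_labels(rec, labels)


def _classify_slow_run(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    a: int,
    b: int,
    D_T: float,
    min_fix_dur_ms: float,
) -> None:
    i = a
    while i <= b:
        j = int(np.searchsorted(t, t[i] + min_fix_dur_ms, side="left"))
        if j > b:
            # run tail shorter than the minimum window: classify as a block
            tail_label = "fixation" if _dispersion(x, y, i, b) <= D_T else "smooth_pursuit"
            labels[i : b + 1] = tail_label
            return
        if _dispersion(x, y, i, j) <= D_T:
            while j + 1 <= b and _dispersion(x, y, i, j + 1) <= D_T:
                j += 1
            labels[i : j + 1] = "fixation"
            i = j + 1
        else:
            labels[i] = "smooth_pursuit"
            i += 1


# ---------------------------------------------------------------------------
# Post-hoc cleanup (off by default; I-VT blips are preserved deliberately)
# ---------------------------------------------------------------------------


def stare_regions(
    segments: Sequence[EventSegment],
    rec: GazeRecording,
    merge_dist_deg: float = 1.0,
) -> list[EventSegment]:
    """Group chronological stare segments into spatially distinct regions.

    Consecutive fixation/pursuit segments whose centroids stay within
    ``merge_dist_deg`` of the running region centroid are one region, so a
    stay split by a threshold blip or a dispersion overflow still counts
    once; a genuine move to a new area starts a new region.  Interleaved
    saccade segments are skipped.
    """
    regions: list[list[EventSegment]] = []
    for seg in segments:
        if seg.label not in ("fixation", "smooth_pursuit", "stare"):
            continue
        if regions:
            cur = regions[-1]
            w = np.array([s.n_samples for s in cur], dtype=float)
            cx = np.average([s.centroid[0] for s in cur], weights=w)
            cy = np.average([s.centroid[1] for s in cur], weights=w)
            if np.hypot(seg.centroid[0] - cx, seg.centroid[1] - cy) <= merge_dist_deg:
                cur.append(seg)
                continue
        regions.append([seg])
    return [
        EventSegment.from_span(rec, "stare", group[0].start_index, group[-1].end_index)
        for group in regions
    ]


def merge_short_segments(
    segments: Sequence[EventSegment],
    rec: GazeRecording,
    min_duration_ms: float,
) -> list[EventSegment]:
    """Merge segments shorter than ``min_duration_ms`` into the longer
    neighbouring segment (ties toward the earlier one), then re-collapse."""
    if not segments:
        return []
    segs = list(segments)
    changed = True
    while changed:
        changed = False
        for k, seg in enumerate(segs):
            if seg.duration >= min_duration_ms or len(segs) == 1:
                continue
            prev_seg = segs[k - 1] if k > 0 else None
            next_seg = segs[k + 1] if k + 1 < len(segs) else None
            if prev_seg is None:
                target = next_seg
            elif next_seg is None:
                target = prev_seg
            else:
                target = prev_seg if prev_seg.duration >= next_seg.duration else next_seg
            if target is None or target.label == seg.label:
                continue
            segs[k] = EventSegment.from_span(
                rec, target.label, seg.start_index, seg.end_index
            )
            changed = True
        if changed:
            # re-collapse adjacent equal labels
            merged: list[EventSegment] = []
            for seg in segs:
                if merged and merged[-1].label == seg.label:
                    merged[-1] = EventSegment.from_span(
                        rec, seg.label, merged[-1].start_index, seg.end_index
                    )
                else:
                    merged.append(seg)
            segs = merged
    return segs
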