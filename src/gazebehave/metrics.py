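"""Detector-evaluation scores: FQnS, FQlS, pursuit scores, RC sweeps, F1.

The fixation scores compare detected fixations against a stimulus-defined
intended-fixation signal:

FQnS (fixation qualitative score)
    Percentage of eligible stimulus-fixation samples for which a detected
    fixation is active at that time with its centroid within ``dist_tol``
    of the stimulus position.  Samples within a saccadic-latency window
    (default 200 ms) after each stimulus fixation onset are excluded, since
    the eye cannot yet have arrived.
FQlS (fixation quantitative score)
    Mean Euclidean distance (degrees) between active detected-fixation
    centroids and the stimulus fixation position; lower is better.

The pursuit scores are the analogous qualitative pair for smooth pursuit
(position- and velocity-agreement variants); the literature names them
inconsistently (PQnS vs PQlS_P / PQlS_V), so this module exposes the
neutral names ``pursuit_position_score`` / ``pursuit_velocity_score`` and
keeps both aliases.

Range-Coefficient sweeps re-run a detector over the threshold family
``threshold(RC) = C + RC * Vi * T`` and record a chosen score per RC.
F1 is computed per class at the sample level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .core import EventSegment, GazeRecording, sample_velocities
from .detect import dbscan_iqr, idt, ivdt, ivt
from .simulate import StimulusSignal

__all__ = [
    "fqns",
    "fqls",
    "pursuit_scores",
    "pursuit_position_score",
    "pursuit_velocity_score",
    "RCSweep",
    "rc_sweep",
    "event_f1",
    "read_lund2013_csv",
    "LUND2013_LABELS",
]

SACCADIC_LATENCY_MS = 200.0
DEFAULT_DIST_TOL = 1.5  # deg, mid-foveal


def _check_alignment(detected: Sequence[EventSegment], n: int) -> None:
    if detected and max(s.end_index for s in detected) != n - 1:
        raise ValueError(
            "detected events are not aligned with the stimulus signal "
            f"(events cover {max(s.end_index for s in detected) + 1} samples, "
            f"stimulus has {n}); score on the same sampling grid, e.g. do not "
            "drop samples after the stimulus signal was built"
        )


def _active_fixation_centroids(
    detected: Sequence[EventSegment], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample detected-fixation centroid (NaN where no fixation)."""
    cx = np.full(n, np.nan)
    cy = np.full(n, np.nan)
    for seg in detected:
        if seg.label == "fixation":
            cx[seg.start_index : seg.end_index + 1] = seg.centroid[0]
            cy[seg.start_index : seg.end_index + 1] = seg.centroid[1]
    return cx, cy


def _fixation_eligible(stim: StimulusSignal, latency_ms: float) -> np.ndarray:
    """Stimulus-fixation samples outside the post-onset latency window."""
    is_fix = stim.kind == "fixation"
    eligible = np.zeros(len(stim), dtype=bool)
    onset_t = None
    for i in range(len(stim)):
        if is_fix[i]:
            if i == 0 or not is_fix[i - 1]:
                onset_t = stim.t[i]
            # the first stimulus fixation of a recording needs no latency
            if stim.t[i] - onset_t >= latency_ms or onset_t == stim.t[0]:
                eligible[i] = True
    return eligible


def fqns(
    detected: Sequence[EventSegment],
    stim: StimulusSignal,
    dist_tol: float = DEFAULT_DIST_TOL,
    latency_ms: float = SACCADIC_LATENCY_MS,
) -> float:
    """Fixation qualitative score, percent in [0, 100]."""
    eligible = _fixation_eligible(stim, latency_ms)
    if not np.any(stim.kind == "fixation"):
        raise ValueError("stimulus contains no fixation samples")
    _check_alignment(detected, len(stim))
    cx, cy = _active_fixation_centroids(detected, len(stim))
    dist = np.hypot(cx - stim.x, cy - stim.y)
    matched = eligible & np.isfinite(dist) & (dist <= dist_tol)
    return float(100.0 * matched.sum() / eligible.sum())


def fqls(detected: Sequence[EventSegment], stim: StimulusSignal) -> float:
    """Fixation quantitative score: mean centroid-to-stimulus distance (deg)."""
    is_fix = stim.kind == "fixation"
    _check_alignment(detected, len(stim))
    cx, cy = _active_fixation_centroids(detected, len(stim))
    mask = is_fix & np.isfinite(cx)
    if not mask.any():
        raise ValueError("no detected fixation overlaps the stimulus fixations")
    return float(np.mean(np.hypot(cx[mask] - stim.x[mask], cy[mask] - stim.y[mask])))


def _pursuit_cover(detected: Sequence[EventSegment], n: int) -> np.ndarray:
    covered = np.zeros(n, dtype=bool)
    for seg in detected:
        if seg.label == "smooth_pursuit":
            covered[seg.start_index : seg.end_index + 1] = True
    return covered


def pursuit_position_score(
    detected: Sequence[EventSegment],
    stim: StimulusSignal,
    rec: GazeRecording,
    pos_tol: float = 2.0,
) -> float:
    """Percent of stimulus-pursuit samples covered by detected pursuit with
    the gaze within ``pos_tol`` degrees of the target (alias PQlS_P/PQnS_P)."""
    is_p = stim.kind == "pursuit"
    if not is_p.any():
        raise ValueError("stimulus contains no pursuit samples")
    _check_alignment(detected, len(stim))
    covered = _pursuit_cover(detected, len(stim))
    dist = np.hypot(rec.x - stim.x, rec.y - stim.y)
    ok = covered & is_p & (dist <= pos_tol)
    return float(100.0 * ok.sum() / is_p.sum())


def pursuit_velocity_score(
    detected: Sequence[EventSegment],
    stim: StimulusSignal,
    rec: GazeRecording,
    vel_tol: float = 10.0,
) -> float:
    """Percent of stimulus-pursuit samples covered by detected pursuit with
    gaze speed within ``vel_tol`` deg/s of the target speed (alias PQlS_V)."""
    is_p = stim.kind == "pursuit"
    if not is_p.any():
        raise ValueError("stimulus contains no pursuit samples")
    _check_alignment(detected, len(stim))
    covered = _pursuit_cover(detected, len(stim))
    v_gaze = sample_velocities(rec)
    v_stim = np.hypot(stim.vx, stim.vy)
    ok = covered & is_p & (np.abs(v_gaze - v_stim) <= vel_tol)
    return float(100.0 * ok.sum() / is_p.sum())


def pursuit_scores(
    detected: Sequence[EventSegment],
    stim: StimulusSignal,
    rec: GazeRecording,
    pos_tol: float = 2.0,
    vel_tol: float = 10.0,
) -> tuple[float, float]:
    """(position score, velocity score), both percent in [0, 100]."""
    return (
        pursuit_position_score(detected, stim, rec, pos_tol),
        pursuit_velocity_score(detected, stim, rec, vel_tol),
    )


# ---------------------------------------------------------------------------
# Range-Coefficient sweeps
# ---------------------------------------------------------------------------

def _run_detector(
    algo: str,
    param: str,
    threshold: float,
    rec: GazeRecording,
    fixed: dict,
) -> list[EventSegment]:
    if algo == "ivt":
        return ivt(rec, v_T=threshold)
    if algo == "idt":
        kwargs = {"D_T": fixed.get("D_T", 1.0), "dur_T": fixed.get("dur_T", 100.0)}
        kwargs[param] = threshold
        return idt(rec, **kwargs)
    if algo == "ivdt":
        kwargs = {"v_T": fixed.get("v_T", 30.0), "D_T": fixed.get("D_T", 1.5)}
        kwargs[param] = threshold
        return ivdt(rec, **kwargs)
    if algo == "dbscan":
        return dbscan_iqr(
            rec,
            min_points=int(threshold) if param == "min_points" else fixed.get("min_points", 4),
            eps=threshold if param == "eps" else fixed.get("eps"),
            time_weight=fixed.get("time_weight", 1.0),
        )
    raise ValueError(f"unknown detector {algo!r}")


@dataclass
class RCSweep:
    """One sweep family: threshold(RC) = C + RC * Vi * T, one score per RC."""

    algo: str
    param: str
    T: float
    Vi: float
    C: float
    table: pd.DataFrame  # rc, threshold, score

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def rc_sweep(
    algo: str,
    param: str,
    T: float,
    Vi: float,
    C: float,
    rc_values: Sequence[int],
    rec: GazeRecording,
    stim: StimulusSignal,
    score: str = "fqns",
    fixed: dict | None = None,
    **score_kwargs,
) -> RCSweep:
    """Run a detector over the RC threshold family and score each setting.

    Non-positive thresholds are skipped with a warning.  ``score`` is one
    of fqns, fqls, pursuit_position, pursuit_velocity.
    """
    fixed = dict(fixed or {})
    rows = []
    for rc in rc_values:
        threshold = C + rc * Vi * T
        if threshold <= 0:
            warnings.warn(f"RC={rc} gives non-positive threshold; skipped")
            continue
        detected = _run_detector(algo, param, threshold, rec, fixed)
        if score == "fqns":
            s = fqns(detected, stim, **score_kwargs)
        elif score == "fqls":
            try:
                s = fqls(detected, stim)
            except ValueError:
                s = float("nan")
        elif score == "pursuit_position":
            s = pursuit_position_score(detected, stim, rec, **score_kwargs)
        elif score == "pursuit_velocity":
            s = pursuit_velocity_score(detected, stim, rec, **score_kwargs)
        else:
            raise ValueError(f"unknown score {score!r}")
        rows.append({"rc": rc, "threshold": threshold, "score": s})
    return RCSweep(algo, param, T, Vi, C, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Per-class sample-level F1
# ---------------------------------------------------------------------------


def event_f1(
    predicted: Sequence[str],
    truth: Sequence[str],
    classes: Sequence[str],
) -> pd.DataFrame:
    """Sample-level precision/recall/F1 per class.

    A class absent from the truth labels has undefined F1 and is reported
    as NaN.  Supports both the classical alphabet (fixation / saccade /
    smooth_pursuit) and the behavioural one (stare / move).
    """
    predicted = np.asarray(list(predicted), dtype=object)
    truth = np.asarray(list(truth), dtype=object)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    classes = list(classes)
    p, r, f, support = precision_recall_fscore_support(
        truth, predicted, labels=classes, zero_division=0
    )
    f = np.where(support > 0, f, np.nan)
    p = np.where(support > 0, p, np.nan)
    r = np.where(support > 0, r, np.nan)
    return pd.DataFrame(
        {"class": classes, "precision": p, "recall": r, "f1": f, "support": support}
    ).set_index("class")


# ---------------------------------------------------------------------------
# Lund2013 annotation adapter (optional, user-supplied files)
# ---------------------------------------------------------------------------

#: integer event codes used by the Lund2013 annotated distribution
LUND2013_LABELS = {
    1: "fixation",
    2: "saccade",
    3: "pso",
    4: "smooth_pursuit",
    5: "blink",
    6: "unknown",
}


def read_lund2013_csv(
    path: str | Path,
    unit: str = "degrees",
    nominal_rate: float = 500.0,
) -> tuple[GazeRecording, np.ndarray]:
    """Read a Lund2013-style annotation export (columns t, x, y, label).

    ``label`` holds the integer event codes of that distribution.  Returns
    the recording and per-sample string labels.  Only activates on files
    the user has downloaded; nothing here fetches data.
    """
    df = pd.read_csv(path)
    for col in ("t", "x", "y", "label"):
        if col not in df.columns:
            raise ValueError(f"Lund2013 export {path} missing column {col!r}")
    rec = GazeRecording(
        t=df["t"].to_numpy(dtype=float),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        unit=unit,
        nominal_rate=nominal_rate,
    )
    labels = np.array(
        [LUND2013_LABELS.get(int(code), "unknown") for code in df["label"]],
        dtype=object,
    )
    return rec, labels
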