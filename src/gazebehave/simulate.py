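"""Synthetic oculomotor simulator.

Generates gaze recordings with per-sample ground truth that emulate
screen-based target-following tasks:

* a 4-target box task — targets at the corners of a 27.5 x 15 degree
  rectangle (consecutive visual angles 15, 27.5, 15 degrees), 3 s stays and
  0.1–2 s transitions;
* 6-point tasks — a target moving at 30 deg/s in an up–down or Z-shaped
  pattern, either stopping 3 s at each point or passing through.

The simulated eye tracks the target: stays produce fixation with tremor,
slow drift, and return-biased microsaccades confined to the foveal 1–2
degree region; target motion at pursuit speeds (<= ~30 deg/s) produces
smooth pursuit at a configurable gain with catch-up saccades once the lag
exceeds 2 degrees; faster repositionings produce main-sequence saccades
with a symmetric (triangular-velocity) profile.  Both-eye dropouts are
injected at a configurable rate.  Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import GazeRecording

__all__ = [
    "StimulusScript",
    "OculomotorParams",
    "StimulusSignal",
    "make_script",
    "simulate_gaze",
    "script_to_stimulus_signal",
    "PURSUIT_MAX_SPEED",
]

#: fastest target motion the eye will track smoothly (deg/s); faster
#: transitions elicit saccades instead
PURSUIT_MAX_SPEED = 30.0 + 1e-9

FOUR_TARGET_WAYPOINTS = np.array(
    [
        (-13.75, -7.5),  # T1
        (-13.75, 7.5),   # T2 (15 deg from T1)
        (13.75, 7.5),    # T3 (27.5 deg from T2)
        (13.75, -7.5),   # T4 (15 deg from T3)
    ]
)

SIX_POINT_UPDOWN_WAYPOINTS = np.array(
    [(-10.0, -5.0), (-6.0, 5.0), (-2.0, -5.0), (2.0, 5.0), (6.0, -5.0), (10.0, 5.0)]
)

SIX_POINT_ZSHAPE_WAYPOINTS = np.array(
    [(-10.0, -6.0), (0.0, -6.0), (10.0, -6.0), (-10.0, 6.0), (0.0, 6.0), (10.0, 6.0)]
)


@dataclass
class StimulusScript:
    """Target waypoints with stay/transition timing (the ground-truth plan)."""

    waypoints: np.ndarray  # (k, 2) degrees
    stay_ms: np.ndarray  # (k,)
    transition_ms: np.ndarray  # (k-1,)
    pattern: str = "custom"

    def __post_init__(self) -> None:
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        self.stay_ms = np.asarray(self.stay_ms, dtype=float)
        self.transition_ms = np.asarray(self.transition_ms, dtype=float)
        k = len(self.waypoints)
        if k < 1:
            raise ValueError("script needs at least one waypoint")
        if len(self.stay_ms) != k or len(self.transition_ms) != k - 1:
            raise ValueError("stay_ms must have k entries and transition_ms k-1")
        if np.any(self.stay_ms < 0) or np.any(self.transition_ms < 0):
            raise ValueError("timing must be non-negative")
        for a, b in zip(self.waypoints[:-1], self.waypoints[1:]):
            if np.allclose(a, b):
                raise ValueError("consecutive waypoints must be distinct")

    @property
    def total_ms(self) -> float:
        return float(self.stay_ms.sum() + self.transition_ms.sum())

    def leg_speed(self, leg: int) -> float:
        """Target speed (deg/s) during transition ``leg``."""
        dist = float(np.hypot(*(self.waypoints[leg + 1] - self.waypoints[leg])))
        T = self.transition_ms[leg] / 1000.0
        return math.inf if T == 0 else dist / T


@dataclass
class OculomotorParams:
    """Fixational/pursuit noise model parameters (degrees, Hz, seconds)."""

    tremor_amplitude: float = 0.05  # deg, ~90 Hz jitter
    tremor_frequency: float = 90.0  # Hz
    microsaccade_rate: float = 1.5  # events / s during fixation
    microsaccade_amplitude: float = 0.3  # deg
    return_bias: float = 0.7  # fraction of microsaccades that re-centre
    drift_speed: float = 0.5  # deg/s slow wander
    pursuit_gain: float = 0.95  # eye/target velocity ratio
    saccade_peak_velocity: float = 600.0  # deg/s cap
    dropout_rate: float = 0.02  # both-eye-invalid sample fraction
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tremor_amplitude",
            "tremor_frequency",
            "microsaccade_rate",
            "microsaccade_amplitude",
            "drift_speed",
            "saccade_peak_velocity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.return_bias <= 1:
            raise ValueError("return_bias must be a fraction")
        if not 0 <= self.pursuit_gain <= 1.2:
            raise ValueError("pursuit_gain must be in [0, 1.2]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class StimulusSignal:
    """Per-sample intended behaviour aligned to a recording's timestamps.

    ``kind`` is one of fixation / pursuit / transition; positions are the
    target path in degrees, velocities the target velocity vector (deg/s).
    """

    t: np.ndarray
    kind: np.ndarray  # object array of str
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# Script construction
# ---------------------------------------------------------------------------


def make_script(
    pattern: str,
    transitions_s: tuple[float, ...] | None = None,
    stay_s: float = 3.0,
    speed_deg_s: float = 30.0,
    stop: bool = True,
    waypoints: np.ndarray | None = None,
) -> StimulusScript:
    """Build one of the scripted tasks.

    ``four_target``: rectangle corners with 15 / 27.5 / 15 degree spacings,
    3 s stays, transition times supplied per leg (default 0.5 s each).
    ``six_point_updown`` / ``six_point_zshape``: 30 deg/s target with either
    3 s stops at each point (``stop=True``) or pass-through (``stop=False``).
    ``custom`` requires explicit ``waypoints`` and ``transitions_s``.
    """
    if pattern == "four_target":
        pts = FOUR_TARGET_WAYPOINTS
        if transitions_s is None:
            transitions_s = (0.5, 0.5, 0.5)
        if len(transitions_s) != 3:
            raise ValueError("four_target needs 3 transition times")
        return StimulusScript(
            pts,
            np.full(4, stay_s * 1000.0),
            np.asarray(transitions_s, dtype=float) * 1000.0,
            pattern,
        )
    if pattern in ("six_point_updown", "six_point_zshape"):
        pts = (
            SIX_POINT_UPDOWN_WAYPOINTS
            if pattern == "six_point_updown"
            else SIX_POINT_ZSHAPE_WAYPOINTS
        )
        dists = np.hypot(*np.diff(pts, axis=0).T)
        trans_ms = dists / speed_deg_s * 1000.0
        stays = np.full(len(pts), stay_s * 1000.0 if stop else 0.0)
        if not stop:
            # keep a short initial hold so the recording opens with fixation
            stays[0] = 500.0
        return StimulusScript(pts, stays, trans_ms, pattern)
    if pattern == "custom":
        if waypoints is None or transitions_s is None:
            raise ValueError("custom pattern needs waypoints and transitions_s")
        pts = np.asarray(waypoints, dtype=float)
        return StimulusScript(
            pts,
            np.full(len(pts), stay_s * 1000.0),
            np.asarray(transitions_s, dtype=float) * 1000.0,
            pattern,
        )
    raise ValueError(f"unknown pattern {pattern!r}")


# ---------------------------------------------------------------------------
# Piecewise target path
# ---------------------------------------------------------------------------


def _script_intervals(script: StimulusScript):
    """Yield (kind, t0, t1, leg_or_waypoint_index) in chronological order.

    kind is 'stay' or 'leg'; zero-length intervals are skipped.
    """
    out = []
    t = 0.0
    k = len(script.waypoints)
    for i in range(k):
        if script.stay_ms[i] > 0:
            out.append(("stay", t, t + script.stay_ms[i], i))
            t += script.stay_ms[i]
        if i < k - 1 and script.transition_ms[i] > 0:
            out.append(("leg", t, t + script.transition_ms[i], i))
            t += script.transition_ms[i]
    return out


def target_position(script: StimulusScript, t_ms: np.ndarray) -> np.ndarray:
    """Target (x, y) at each time (clamped to the scripted range)."""
    t_ms = np.atleast_1d(np.asarray(t_ms, dtype=float))
    pos = np.zeros((len(t_ms), 2))
    intervals = _script_intervals(script)
    for n, tm in enumerate(t_ms):
        tm = min(max(tm, 0.0), script.total_ms)
        pos[n] = script.waypoints[-1]
        for kind, t0, t1, idx in intervals:
            if t0 <= tm <= t1:
                if kind == "stay":
                    pos[n] = script.waypoints[idx]
                else:
                    u = (tm - t0) / (t1 - t0)
                    pos[n] = (1 - u) * script.waypoints[idx] + u * script.waypoints[
                        idx + 1
                    ]
                break
    return pos


def script_to_stimulus_signal(script: StimulusScript, rate_hz: float) -> StimulusSignal:
    """Sample the intended behaviour on the simulation timestamp grid."""
    dt_ms = 1000.0 / rate_hz
    n = int(math.floor(script.total_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    kind = np.empty(n, dtype=object)
    x = np.zeros(n)
    y = np.zeros(n)
    vx = np.zeros(n)
    vy = np.zeros(n)
    intervals = _script_intervals(script)
    for i, tm in enumerate(t):
        placed = False
        for k, t0, t1, idx in intervals:
            if t0 <= tm < t1 or (tm == script.total_ms and t1 == script.total_ms):
                placed = True
                if k == "stay":
                    kind[i] = "fixation"
                    x[i], y[i] = script.waypoints[idx]
                else:
                    speed = script.leg_speed(idx)
                    kind[i] = "pursuit" if speed <= PURSUIT_MAX_SPEED else "transition"
                    u = (tm - t0) / (t1 - t0)
                    p = (1 - u) * script.waypoints[idx] + u * script.waypoints[idx + 1]
                    x[i], y[i] = p
                    d = script.waypoints[idx + 1] - script.waypoints[idx]
                    dist = float(np.hypot(*d))
                    vx[i], vy[i] = d / dist * speed
                break
        if not placed:  # numerical tail
            kind[i] = "fixation" if script.stay_ms[-1] > 0 else kind[i - 1]
            x[i], y[i] = script.waypoints[-1]
    return StimulusSignal(t=t, kind=kind, x=x, y=y, vx=vx, vy=vy)


# ---------------------------------------------------------------------------
# Eye trajectory
# ---------------------------------------------------------------------------


def _saccade_duration_ms(amplitude_deg: float, peak_cap: float) -> float:
    """Main-sequence-style duration with a peak-velocity cap.

    Triangular profile => peak velocity = 2 * A / duration.
    """
    dur = 2.2 * amplitude_deg + 21.0
    if peak_cap > 0:
        dur = max(dur, 2000.0 * amplitude_deg / peak_cap)
    return dur


def _saccade_progress(u: float) -> float:
    """Normalized displacement for a symmetric triangular velocity profile."""
    if u <= 0.5:
        return 2.0 * u * u
    return 1.0 - 2.0 * (1.0 - u) ** 2


def simulate_gaze(
    script: StimulusScript,
    rate_hz: float,
    ocul: OculomotorParams | None = None,
) -> tuple[GazeRecording, np.ndarray]:
    """Simulate an eye following the scripted target.

    Returns the recording (degrees, no geometry attached) and per-sample
    truth labels from {fixation, smooth_pursuit, saccade}.  Fixational
    micromovements (tremor, drift, microsaccades) are labelled fixation;
    catch-up saccades during pursuit are labelled saccade.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if len(script.waypoints) == 0:
        raise ValueError("empty script")
    ocul = ocul or OculomotorParams()
    rng = np.random.default_rng(ocul.seed)
    dt_ms = 1000.0 / rate_hz
    dt_s = dt_ms / 1000.0
    n = int(math.floor(script.total_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms

    # --- build the noise-free eye timeline: (label, t0, t1, pos_fn) -------
    events: list[tuple[str, float, float, Callable[[float], np.ndarray]]] = []

    def hold(p: np.ndarray) -> Callable[[float], np.ndarray]:
        p = p.copy()
        return lambda tm: p

    def line(p: np.ndarray, q: np.ndarray, t0: float, t1: float):
        p, q = p.copy(), q.copy()
        return lambda tm: p + (q - p) * _saccade_progress(
            min(max((tm - t0) / (t1 - t0), 0.0), 1.0)
        )

    def ramp(p: np.ndarray, v: np.ndarray, t0: float):
        p, v = p.copy(), v.copy()
        return lambda tm: p + v * (tm - t0) / 1000.0

    eye = script.waypoints[0].astype(float).copy()
    for kind, t0, t1, idx in _script_intervals(script):
        if kind == "stay":
            target = script.waypoints[idx]
            gap = float(np.hypot(*(target - eye)))
            if gap > 0.5:
                # correction saccade onto the target at stay onset
                dur = min(_saccade_duration_ms(gap, ocul.saccade_peak_velocity), t1 - t0)
                events.append(("saccade", t0, t0 + dur, line(eye, target, t0, t0 + dur)))
                if t0 + dur < t1:
                    events.append(("fixation", t0 + dur, t1, hold(target)))
            else:
                events.append(("fixation", t0, t1, hold(eye)))
            eye = target.astype(float).copy()
            continue
        # transition leg
        p = script.waypoints[idx]
        q = script.waypoints[idx + 1]
        d = q - p
        dist = float(np.hypot(*d))
        direction = d / dist
        speed = script.leg_speed(idx)
        if speed <= PURSUIT_MAX_SPEED:
            # pursuit at gain g; catch-up saccade when lag exceeds 2 deg
            g = ocul.pursuit_gain
            tc = t0
            eye_pos = eye.copy()
            lag_rate = abs(1.0 - g) * speed  # deg/s
            while tc < t1:
                if lag_rate <= 1e-9:
                    events.append(
                        ("smooth_pursuit", tc, t1, ramp(eye_pos, direction * speed * g, tc))
                    )
                    eye_pos = eye_pos + direction * speed * g * (t1 - tc) / 1000.0
                    tc = t1
                    break
                t_lag = 2.0 / lag_rate * 1000.0  # ms until 2 deg of lag
                t_end = min(tc + t_lag, t1)
                events.append(
                    ("smooth_pursuit", tc, t_end, ramp(eye_pos, direction * speed * g, tc))
                )
                eye_pos = eye_pos + direction * speed * g * (t_end - tc) / 1000.0
                tc = t_end
                if tc >= t1:
                    break
                # catch-up saccade closes the accumulated lag
                tgt_now = target_position(script, np.array([tc]))[0]
                amp = float(np.hypot(*(tgt_now - eye_pos)))
                dur = min(_saccade_duration_ms(amp, ocul.saccade_peak_velocity), t1 - tc)
                events.append(("saccade", tc, tc + dur, line(eye_pos, tgt_now, tc, tc + dur)))
                eye_pos = tgt_now.copy()
                tc += dur
            eye = eye_pos
        else:
            dur = min(_saccade_duration_ms(dist, ocul.saccade_peak_velocity), t1 - t0)
            events.append(("saccade", t0, t0 + dur, line(eye, q, t0, t0 + dur)))
            if t0 + dur < t1:
                events.append(("fixation", t0 + dur, t1, hold(q)))
            eye = q.astype(float).copy()

    # --- sample the timeline ---------------------------------------------
    # positions are sampled at t_i; the label of sample i describes the
    # motion over its sampling interval (t_{i-1}, t_i], i.e. the event with
    # the largest overlap, matching what sample-to-sample velocity measures
    starts = np.array([e[1] for e in events])
    labels = np.empty(n, dtype=object)
    base = np.zeros((n, 2))
    for i, tm in enumerate(t):
        k = int(np.searchsorted(starts, tm, side="right")) - 1
        k = max(k, 0)
        base[i] = events[k][3](tm)
        if i == 0:
            labels[i] = events[k][0]
            continue
        lo = tm - dt_ms
        best, best_ov = events[k][0], -1.0
        for kk in range(k, -1, -1):
            label, t0, t1, _ = events[kk]
            if t1 <= lo:
                break
            ov = min(t1, tm) - max(t0, lo)
            if ov > best_ov:  # ties keep the later event
                best_ov, best = ov, label
        labels[i] = best

    # --- fixational noise --------------------------------------------------
    # tremor: ~90 Hz sinusoid with random phases (aliased at low rates, as a
    # real tracker would see it)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    tremor = ocul.tremor_amplitude * np.column_stack(
        [
            np.sin(2 * np.pi * ocul.tremor_frequency * t / 1000.0 + phases[0]),
            np.sin(2 * np.pi * ocul.tremor_frequency * t / 1000.0 + phases[1]),
        ]
    )
    # drift: Ornstein-Uhlenbeck position noise; stationary std scales with
    # drift_speed (0.3 s characteristic excursion time), tau = 0.7 s
    tau = 0.7
    sigma_d = ocul.drift_speed * 0.3
    a = math.exp(-dt_s / tau)
    drift = np.zeros((n, 2))
    step_sd = sigma_d * math.sqrt(max(1.0 - a * a, 0.0))
    shocks = rng.normal(0.0, 1.0, size=(n, 2)) * step_sd
    for i in range(1, n):
        drift[i] = a * drift[i - 1] + shocks[i]
    # microsaccades: Poisson events during fixation; return-biased jumps,
    # clamped so the fixational excursion stays inside the foveal ~1.5 deg
    ms_offset = np.zeros((n, 2))
    cur = np.zeros(2)
    p_event = ocul.microsaccade_rate * dt_s
    u_events = rng.uniform(size=n)
    for i in range(n):
        if labels[i] == "fixation" and u_events[i] < p_event:
            total = cur + drift[i]
            if rng.uniform() < ocul.return_bias or np.hypot(*total) > 1.2:
                cur = cur - 0.8 * total
            else:
                ang = rng.uniform(0, 2 * np.pi)
                amp = ocul.microsaccade_amplitude * rng.uniform(0.5, 1.5)
                cur = cur + amp * np.array([math.cos(ang), math.sin(ang)])
        ms_offset[i] = cur

    noise = tremor + drift + ms_offset
    fixation_mask = (labels == "fixation")[:, None]
    pursuit_mask = (labels == "smooth_pursuit")[:, None]
    # pursuit keeps tremor/drift (no microsaccade offsets) at reduced weight
    pos = base + noise * fixation_mask + (tremor + drift) * 0.5 * pursuit_mask

    # --- binocular dropouts ------------------------------------------------
    left_valid = np.ones(n, dtype=bool)
    right_valid = np.ones(n, dtype=bool)
    if ocul.dropout_rate > 0:
        drop = rng.uniform(size=n) < ocul.dropout_rate
        left_valid[drop] = False
        right_valid[drop] = False
        # trackers freeze/garble position during blinks; freeze at last value
        for i in np.nonzero(drop)[0]:
            if i > 0:
                pos[i] = pos[i - 1]

    rec = GazeRecording(
        t=t,
        x=pos[:, 0],
        y=pos[:, 1],
        left_valid=left_valid,
        right_valid=right_valid,
        geometry=None,
        unit="degrees",
        nominal_rate=rate_hz,
    )
    return rec, labels
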