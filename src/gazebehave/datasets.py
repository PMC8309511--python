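"""Bundled synthetic stare/move window corpus.

A reproducible recipe that mixes the scripted tasks into a balanced
training corpus for the behaviour classifiers:

* multi-target box runs (fast transitions -> clean saccades),
* 6-point pursuit runs, both stopping and pass-through (smooth pursuit
  arcs plus catch-up saccades),
* search-like runs over random waypoints with short stays (dense saccade
  coverage, varied amplitudes).

Everything is generated at run time from one seed; no data files ship with
the package.
"""

from __future__ import annotations

import numpy as np

from .simulate import OculomotorParams, make_script, simulate_gaze
from .windows import WindowDataset, WindowSpec, build_dataset

__all__ = ["make_training_recordings", "bundled_dataset"]


def _search_script(rng: np.random.Generator, n_waypoints: int = 24):
    """Random-walk waypoint script emulating search behaviour."""
    pts = [rng.uniform(-12, 12, size=2)]
    while len(pts) < n_waypoints:
        step = rng.uniform(4, 14) * _unit(rng)
        nxt = np.clip(pts[-1] + step, -14, 14)
        if np.hypot(*(nxt - pts[-1])) > 1.0:
            pts.append(nxt)
    trans = rng.uniform(0.12, 0.25, size=len(pts) - 1)
    return make_script(
        "custom",
        waypoints=np.array(pts),
        transitions_s=tuple(trans),
        stay_s=0.35,
    )


def _unit(rng: np.random.Generator) -> np.ndarray:
    ang = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(ang), np.sin(ang)])


def make_training_recordings(
    seed: int = 0,
    rate_hz: float = 40.0,
    n_search: int = 160,
    n_pursuit: int = 10,
    n_box: int = 6,
) -> list[tuple]:
    """Simulate the corpus recordings; returns [(recording, truth), ...]."""
    rng = np.random.default_rng(seed)
    out = []

    def sim(script):
        ocul = OculomotorParams(seed=int(rng.integers(0, 2**31 - 1)))
        rec, truth = simulate_gaze(script, rate_hz, ocul)
        out.append((rec, truth))

    for _ in range(n_search):
        sim(_search_script(rng))
    for k in range(n_pursuit):
        pattern = "six_point_updown" if k % 2 == 0 else "six_point_zshape"
        sim(make_script(pattern, stop=bool(k % 4 < 2)))
    for _ in range(n_box):
        trans = tuple(rng.choice([0.1, 0.2, 0.5], size=3))
        sim(make_script("four_target", transitions_s=trans))
    return out


def bundled_dataset(
    n_per_class: int = 4000,
    split: float = 0.5,
    seed: int = 0,
    rate_hz: float = 40.0,
    spec: WindowSpec | None = None,
) -> tuple[WindowDataset, WindowDataset]:
    """Build the balanced bundled corpus (train, validation).

    ``n_per_class`` counts windows per class over both splits; class sizes
    are exactly balanced.  The corpus size scales with ``n_per_class`` so
    small values stay cheap.
    """
    spec = spec or WindowSpec()
    scale = max(n_per_class / 4000.0, 0.05)
    recs = make_training_recordings(
        seed=seed,
        rate_hz=rate_hz,
        n_search=max(int(np.ceil(160 * scale)), 2),
        n_pursuit=max(int(np.ceil(10 * scale)), 2),
        n_box=max(int(np.ceil(6 * scale)), 1),
    )
    return build_dataset(recs, spec, n_per_class, split=split, seed=seed)
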