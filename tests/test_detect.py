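"""Detector unit tests against independent brute-force oracles."""

import numpy as np
import pytest
from sklearn.cluster import DBSCAN as SkDBSCAN

from gazebehave.core import sample_velocities
from gazebehave.detect import (
    DetectorParams,
    dbscan_eps_iqr,
    dbscan_labels,
    dbscan_iqr,
    idt,
    ivdt,
    ivt,
)
from gazebehave.detect import _dbscan_features

from conftest import make_recording, random_trace


# ---------------------------------------------------------------------------
# Oracles (independent reimplementations used only by tests)
# ---------------------------------------------------------------------------


def oracle_ivt_labels(rec, v_T):
    v = sample_velocities(rec)
    return ["fixation" if vi < v_T else "saccade" for vi in v]


def oracle_idt_segments(rec, D_T, dur_T):
    """Exhaustive window growth with explicit loops; returns
    (label, start, end) tuples partitioning the samples."""
    n = len(rec)

    def disp(i, j):
        xs = rec.x[i : j + 1]
        ys = rec.y[i : j + 1]
        return (max(xs) - min(xs)) + (max(ys) - min(ys))

    windows = []
    i = 0
    while i < n:
        j = None
        for k in range(i, n):
            if rec.t[k] - rec.t[i] >= dur_T:
                j = k
                break
        if j is None:
            break
        if disp(i, j) <= D_T:
            while j + 1 < n and disp(i, j + 1) <= D_T:
                j += 1
            windows.append((i, j))
            i = j + 1
        else:
            i += 1
    segs = []
    pos = 0
    for lo, hi in windows:
        if lo > pos:
            segs.append(("saccade", pos, lo - 1))
        segs.append(("fixation", lo, hi))
        pos = hi + 1
    if pos < n:
        segs.append(("saccade", pos, n - 1))
    return segs


def oracle_dbscan(points, eps, min_points):
    """Naive quadratic DBSCAN with the lowest-index-core border rule."""
    n = len(points)
    neighbors = [
        [q for q in range(n) if np.linalg.norm(points[p] - points[q]) <= eps]
        for p in range(n)
    ]
    core = [len(neighbors[p]) >= min_points for p in range(n)]
    labels = [-1] * n
    cid = 0
    for start in range(n):
        if not core[start] or labels[start] != -1:
            continue
        frontier = [start]
        labels[start] = cid
        while frontier:
            p = frontier.pop()
            for q in neighbors[p]:
                if core[q] and labels[q] == -1:
                    labels[q] = cid
                    frontier.append(q)
        cid += 1
    for p in range(n):
        if core[p]:
            continue
        core_nb = [q for q in neighbors[p] if core[q]]
        labels[p] = labels[core_nb[0]] if core_nb else -1
    return labels


def oracle_ivdt_labels(rec, v_T, D_T, min_fix_dur_ms=100.0):
    """Staged oracle: velocity gate, then per-run dispersion window march."""
    n = len(rec)
    v = sample_velocities(rec)
    labels = ["saccade" if vi >= v_T else None for vi in v]

    def disp(i, j):
        xs = rec.x[i : j + 1]
        ys = rec.y[i : j + 1]
        return (max(xs) - min(xs)) + (max(ys) - min(ys))

    runs = []
    i = 0
    while i < n:
        if labels[i] is None:
            a = i
            while i < n and labels[i] is None:
                i += 1
            runs.append((a, i - 1))
        else:
            i += 1
    for a, b in runs:
        i = a
        while i <= b:
            j = None
            for k in range(i, b + 1):
                if rec.t[k] - rec.t[i] >= min_fix_dur_ms:
                    j = k
                    break
            if j is None:
                lab = "fixation" if disp(i, b) <= D_T else "smooth_pursuit"
                for k in range(i, b + 1):
                    labels[k] = lab
                break
            if disp(i, j) <= D_T:
                while j + 1 <= b and disp(i, j + 1) <= D_T:
                    j += 1
                for k in range(i, j + 1):
                    labels[k] = "fixation"
                i = j + 1
            else:
                labels[i] = "smooth_pursuit"
                i += 1
    return labels


def expand(segments, n):
    out = [None] * n
    for s in segments:
        for k in range(s.start_index, s.end_index + 1):
            out[k] = s.label
    return out


# ---------------------------------------------------------------------------
# I-VT
# ---------------------------------------------------------------------------


class TestIvt:
    def test_stationary_trace_is_one_fixation(self):
        rec = make_recording(np.full(20, 3.0), np.full(20, -1.0))
        segs = ivt(rec, 5.0)
        assert len(segs) == 1
        assert segs[0].label == "fixation"
        assert segs[0].start_index == 0 and segs[0].end_index == 19

    def test_step_displacement_splits_fixation(self):
        x = np.zeros(12)
        x[6:] = 5.0  # one-sample jump at index 6: 5 deg / 25 ms = 200 deg/s
        rec = make_recording(x, np.zeros(12))
        segs = ivt(rec, 50.0)
        assert [(s.label, s.start_index, s.end_index) for s in segs] == [
            ("fixation", 0, 5),
            ("saccade", 6, 6),
            ("fixation", 7, 11),
        ]

    def test_matches_per_sample_oracle_on_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            rec = random_trace(rng)
            v_T = rng.uniform(5, 200)
            assert expand(ivt(rec, v_T), len(rec)) == oracle_ivt_labels(rec, v_T)

    def test_fixation_sample_count_nondecreasing_in_threshold(self):
        rng = np.random.default_rng(4)
        rec = random_trace(rng, n=50)
        counts = []
        for v_T in np.linspace(1.0, 300.0, 50):
            counts.append(
                sum(s.n_samples for s in ivt(rec, v_T) if s.label == "fixation")
            )
        assert all(b >= a for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# I-DT
# ---------------------------------------------------------------------------


class TestIdt:
    def test_single_point_trace_is_one_fixation(self):
        rec = make_recording(np.full(10, 1.0), np.full(10, 1.0))
        segs = idt(rec, 1.0, 100.0)
        assert [s.label for s in segs] == ["fixation"]

    def test_two_clusters_with_jump(self):
        x = np.concatenate([np.zeros(7) + 0.01 * np.arange(7), np.full(8, 10.0)])
        rec = make_recording(x, np.zeros(15))
        segs = idt(rec, 1.0, 100.0)
        fix = [s for s in segs if s.label == "fixation"]
        assert len(fix) == 2
        assert [
            (s.label, s.start_index, s.end_index) for s in segs
        ] == oracle_idt_segments(rec, 1.0, 100.0)

    def test_dispersion_below_noise_yields_no_fixations(self):
        rng = np.random.default_rng(9)
        rec = make_recording(
            rng.normal(0, 1.0, 40), rng.normal(0, 1.0, 40)
        )
        segs = idt(rec, 0.01, 100.0)
        assert all(s.label == "saccade" for s in segs)

    def test_matches_exhaustive_oracle_on_random_traces(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            rec = random_trace(rng)
            D_T = rng.uniform(0.3, 5.0)
            dur_T = rng.uniform(40, 200)
            assert [
                (s.label, s.start_index, s.end_index) for s in idt(rec, D_T, dur_T)
            ] == oracle_idt_segments(rec, D_T, dur_T)

    def test_emitted_fixations_satisfy_both_thresholds(self):
        rng = np.random.default_rng(33)
        rec = random_trace(rng, n=50)
        D_T, dur_T = 2.0, 100.0
        for s in idt(rec, D_T, dur_T):
            if s.label != "fixation":
                continue
            xs = rec.x[s.start_index : s.end_index + 1]
            ys = rec.y[s.start_index : s.end_index + 1]
            assert (xs.max() - xs.min()) + (ys.max() - ys.min()) <= D_T + 1e-12
            assert s.duration >= dur_T


# ---------------------------------------------------------------------------
# DBSCAN with IQR
# ---------------------------------------------------------------------------


class TestDbscan:
    def test_eps_is_q3_of_distances_to_centroid(self):
        # four collinear points at distances 1.5,0.5,0.5,1.5 from centroid
        rec = make_recording([0.0, 1.0, 2.0, 3.0], np.zeros(4))
        d = np.abs(np.array([0.0, 1.0, 2.0, 3.0]) - 1.5)
        assert dbscan_eps_iqr(rec) == pytest.approx(np.percentile(d, 75))

    def test_eps_zero_for_coincident_points(self):
        t = np.arange(4) * 25.0
        from gazebehave.core import GazeRecording

        rec = GazeRecording(t=t, x=np.ones(4), y=np.ones(4))
        assert dbscan_eps_iqr(rec) == 0.0
        with pytest.raises(ValueError, match="eps"):
            dbscan_iqr(rec, 2)

    def test_eps_translation_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-5, 5, 20)
        y = rng.uniform(-5, 5, 20)
        r1 = make_recording(x, y)
        r2 = make_recording(x + 100.0, y - 42.0)
        assert dbscan_eps_iqr(r1) == pytest.approx(dbscan_eps_iqr(r2))

    def test_single_dense_cluster_is_one_fixation(self):
        rng = np.random.default_rng(5)
        rec = make_recording(rng.normal(0, 0.1, 12), rng.normal(0, 0.1, 12))
        segs = dbscan_iqr(rec, 4, eps=1.0)
        assert [s.label for s in segs] == ["fixation"]

    def test_two_separated_clusters_match_naive_oracle(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.2, 15), rng.normal(10, 0.2, 15)])
        y = np.concatenate([rng.normal(0, 0.2, 15), rng.normal(0, 0.2, 15)])
        rec = make_recording(x, y)
        eps = 1.0
        got = dbscan_labels(rec, 4, time_weight=0.0, eps=eps)
        pts = np.column_stack([x, y, np.zeros_like(x)])
        want = oracle_dbscan(pts, eps, 4)
        assert list(got) == want

    def test_matches_sklearn_core_points(self):
        """Independent cross-check: core-point clustering agrees with sklearn
        up to relabeling (border assignment is implementation-defined)."""
        rng = np.random.default_rng(7)
        rec = random_trace(rng, n=50)
        eps = 2.0
        pts = _dbscan_features(rec, 1.0)
        ours = dbscan_labels(rec, 4, time_weight=1.0, eps=eps)
        sk = SkDBSCAN(eps=eps, min_samples=4).fit(pts)
        core = np.zeros(len(pts), dtype=bool)
        core[sk.core_sample_indices_] = True
        # same core set and same core partition
        d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
        n_nb = (d2 <= eps * eps).sum(axis=1)
        assert np.array_equal(core, n_nb >= 4)
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                if core[a] and core[b]:
                    assert (ours[a] == ours[b]) == (sk.labels_[a] == sk.labels_[b])

    def test_min_points_changes_fixation_count(self):
        rng = np.random.default_rng(8)
        from gazebehave.simulate import OculomotorParams, make_script, simulate_gaze

        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, _ = simulate_gaze(script, 40.0, OculomotorParams(seed=12))
        n_small = sum(s.label == "fixation" for s in dbscan_iqr(rec, 3, eps=0.3))
        n_large = sum(s.label == "fixation" for s in dbscan_iqr(rec, 30, eps=0.3))
        assert n_small != n_large


# ---------------------------------------------------------------------------
# I-VDT
# ---------------------------------------------------------------------------


class TestIvdt:
    def test_stationary_trace_is_fixation_only(self):
        rec = make_recording(np.full(30, 2.0), np.full(30, 2.0))
        segs = ivdt(rec, 50.0, 1.5)
        assert [s.label for s in segs] == ["fixation"]

    def test_hold_ramp_hold_yields_fix_pursuit_fix(self):
        # 0.5 s hold, 1 s ramp at 20 deg/s, 0.5 s hold; 40 Hz
        hold1 = np.zeros(20)
        ramp = 20.0 * np.arange(1, 41) / 40.0
        hold2 = np.full(20, 20.0)
        x = np.concatenate([hold1, ramp, hold2])
        rec = make_recording(x, np.zeros_like(x))
        segs = ivdt(rec, 50.0, 1.5)
        kinds = [s.label for s in segs]
        assert kinds == ["fixation", "smooth_pursuit", "fixation"]

    def test_matches_staged_oracle_on_random_traces(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            rec = random_trace(rng)
            v_T = rng.uniform(20, 150)
            D_T = rng.uniform(0.5, 4.0)
            assert expand(ivdt(rec, v_T, D_T), len(rec)) == oracle_ivdt_labels(
                rec, v_T, D_T
            )

    def test_tiny_dispersion_threshold_fragments_events(self):
        rng = np.random.default_rng(14)
        from gazebehave.simulate import OculomotorParams, make_script, simulate_gaze

        script = make_script("six_point_updown", stop=True)
        rec, _ = simulate_gaze(script, 40.0, OculomotorParams(seed=15))
        few = ivdt(rec, 50.0, 3.0)
        # dispersion threshold just below the fixational noise scale
        many = ivdt(rec, 50.0, 0.2)
        n_events = lambda segs: sum(
            s.label in ("fixation", "smooth_pursuit") for s in segs
        )
        assert n_events(many) > 2 * n_events(few)


# ---------------------------------------------------------------------------
# Shared partition property
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("detector", ["ivt", "idt", "dbscan", "ivdt"])
def test_every_detector_partitions_samples(detector):
    rng = np.random.default_rng(99)
    for _ in range(20):
        rec = random_trace(rng)
        if detector == "ivt":
            segs = ivt(rec, 40.0)
        elif detector == "idt":
            segs = idt(rec, 2.0, 100.0)
        elif detector == "dbscan":
            segs = dbscan_iqr(rec, 4, eps=1.5)
        else:
            segs = ivdt(rec, 60.0, 2.0)
        assert segs[0].start_index == 0
        assert segs[-1].end_index == len(rec) - 1
        for a, b in zip(segs, segs[1:]):
            assert b.start_index == a.end_index + 1


def test_detector_params_validation():
    with pytest.raises(ValueError):
        DetectorParams(velocity_threshold=-1)
    with pytest.raises(ValueError):
        DetectorParams(eps=0.0)
    with pytest.raises(ValueError):
        DetectorParams(min_points=1)


class TestStareRegions:
    def test_blip_split_stay_counts_once(self):
        from gazebehave.detect import stare_regions
        from gazebehave.core import EventSegment

        # one stay split in two by a saccade blip, then a move to a new area
        x = np.concatenate([np.zeros(10), [0.2], np.full(10, 0.1), np.full(10, 12.0)])
        rec = make_recording(x, np.zeros(len(x)))
        segs = [
            EventSegment.from_span(rec, "fixation", 0, 9),
            EventSegment.from_span(rec, "saccade", 10, 10),
            EventSegment.from_span(rec, "fixation", 11, 20),
            EventSegment.from_span(rec, "fixation", 21, 30),
        ]
        regions = stare_regions(segs, rec)
        assert len(regions) == 2
        assert regions[0].centroid[0] == pytest.approx(0.05, abs=0.1)
        assert regions[1].centroid[0] == pytest.approx(12.0, abs=0.1)

    def test_distinct_targets_stay_distinct(self):
        from gazebehave.detect import stare_regions
        from gazebehave.simulate import OculomotorParams, make_script, simulate_gaze

        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, _ = simulate_gaze(script, 40.0, OculomotorParams(seed=0, dropout_rate=0.0))
        assert len(stare_regions(ivt(rec, 30.0), rec)) == 4
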