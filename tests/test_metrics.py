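"""FQnS/FQlS, pursuit scores, RC sweeps, and per-class F1."""

import numpy as np
import pytest

from gazebehave.core import EventSegment, segments_from_labels
from gazebehave.metrics import (
    event_f1,
    fqls,
    fqns,
    pursuit_scores,
    rc_sweep,
    read_lund2013_csv,
)
from gazebehave.simulate import (
    OculomotorParams,
    make_script,
    script_to_stimulus_signal,
    simulate_gaze,
)

from conftest import make_recording


def quiet():
    return OculomotorParams(
        tremor_amplitude=0.0,
        microsaccade_rate=0.0,
        drift_speed=0.0,
        dropout_rate=0.0,
        pursuit_gain=1.0,
        seed=0,
    )


def truth_replay_segments(rec, truth):
    """The truth-replay 'detector': segments straight from ground truth."""
    return segments_from_labels(rec, truth)


class TestFqns:
    def test_truth_replay_scores_100_on_fixation_stimulus(self):
        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, truth = simulate_gaze(script, 40.0, quiet())
        stim = script_to_stimulus_signal(script, 40.0)
        assert fqns(truth_replay_segments(rec, truth), stim) == pytest.approx(100.0)

    def test_half_coverage_scores_50(self):
        # stimulus: one fixation over 40 samples; detector covers first 20
        n = 40
        rec = make_recording(np.zeros(n), np.zeros(n))
        script = make_script(
            "custom", waypoints=np.array([[0.0, 0.0], [5.0, 0.0]]),
            transitions_s=(0.0,), stay_s=n / 40.0 / 2,
        )
        stim = script_to_stimulus_signal(script, 40.0)
        stim.kind[:] = "fixation"
        stim.x[:] = 0.0
        stim.y[:] = 0.0
        segs = [
            EventSegment("fixation", 0, n // 2 - 1, (0.0, 0.0), 500.0),
            EventSegment("saccade", n // 2, len(stim) - 1, (0.0, 0.0), 500.0),
        ]
        got = fqns(segs, stim, latency_ms=0.0)
        assert got == pytest.approx(100.0 * (n // 2) / len(stim))

    def test_stimulus_without_fixation_rejected(self):
        script = make_script("six_point_updown", stop=False)
        stim = script_to_stimulus_signal(script, 40.0)
        stim.kind[:] = "pursuit"
        with pytest.raises(ValueError, match="fixation"):
            fqns([], stim)


class TestFqls:
    def test_exact_detector_scores_zero(self):
        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, truth = simulate_gaze(script, 40.0, quiet())
        stim = script_to_stimulus_signal(script, 40.0)
        assert fqls(truth_replay_segments(rec, truth), stim) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_constant_offset_detector_scores_offset(self):
        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, truth = simulate_gaze(script, 40.0, quiet())
        stim = script_to_stimulus_signal(script, 40.0)
        segs = truth_replay_segments(rec, truth)
        shifted = [
            EventSegment(
                s.label, s.start_index, s.end_index,
                (s.centroid[0] + 1.0, s.centroid[1]), s.duration,
            )
            for s in segs
        ]
        assert fqls(shifted, stim) == pytest.approx(1.0)

    def test_translation_of_both_signals_invariant(self):
        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, truth = simulate_gaze(script, 40.0, quiet())
        stim = script_to_stimulus_signal(script, 40.0)
        segs = truth_replay_segments(rec, truth)
        base = fqls(segs, stim)
        stim.x += 11.0
        shifted = [
            EventSegment(
                s.label, s.start_index, s.end_index,
                (s.centroid[0] + 11.0, s.centroid[1]), s.duration,
            )
            for s in segs
        ]
        assert fqls(shifted, stim) == pytest.approx(base)


class TestPursuitScores:
    def test_perfect_pursuit_maximal(self):
        script = make_script("six_point_updown", stop=False)
        rec, truth = simulate_gaze(script, 40.0, quiet())
        stim = script_to_stimulus_signal(script, 40.0)
        pos, vel = pursuit_scores(truth_replay_segments(rec, truth), stim, rec)
        assert pos > 95.0 and vel > 90.0

    def test_no_pursuit_detected_minimal(self):
        script = make_script("six_point_updown", stop=False)
        rec, truth = simulate_gaze(script, 40.0, quiet())
        stim = script_to_stimulus_signal(script, 40.0)
        segs = [EventSegment("fixation", 0, len(rec) - 1, (0.0, 0.0), 1.0)]
        pos, vel = pursuit_scores(segs, stim, rec)
        assert pos == 0.0 and vel == 0.0

    def test_stimulus_without_pursuit_rejected(self):
        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, truth = simulate_gaze(script, 40.0, quiet())
        stim = script_to_stimulus_signal(script, 40.0)
        with pytest.raises(ValueError, match="pursuit"):
            pursuit_scores(truth_replay_segments(rec, truth), stim, rec)


class TestRcSweep:
    def test_zero_vi_constant_score(self):
        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, _ = simulate_gaze(script, 40.0, OculomotorParams(seed=1))
        stim = script_to_stimulus_signal(script, 40.0)
        sweep = rc_sweep("ivt", "v_T", T=30.0, Vi=0.0, C=30.0,
                         rc_values=range(1, 8), rec=rec, stim=stim)
        assert sweep.table["threshold"].nunique() == 1
        assert sweep.table["score"].nunique() == 1

    def test_table_matches_manual_loop(self):
        from gazebehave.detect import ivt

        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, _ = simulate_gaze(script, 40.0, OculomotorParams(seed=1))
        stim = script_to_stimulus_signal(script, 40.0)
        T, Vi, C = 10.0, 0.5, 5.0
        sweep = rc_sweep("ivt", "v_T", T, Vi, C, range(1, 6), rec, stim)
        for _, row in sweep.table.iterrows():
            want = fqns(ivt(rec, row["threshold"]), stim)
            assert row["score"] == pytest.approx(want)

    def test_nonpositive_threshold_skipped_with_warning(self):
        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, _ = simulate_gaze(script, 40.0, OculomotorParams(seed=1))
        stim = script_to_stimulus_signal(script, 40.0)
        with pytest.warns(UserWarning, match="non-positive"):
            sweep = rc_sweep("ivt", "v_T", T=10.0, Vi=1.0, C=-25.0,
                             rc_values=[1, 2, 3, 4], rec=rec, stim=stim)
        assert list(sweep.table["rc"]) == [3, 4]

    def test_idt_sweeps_dispersion_and_duration_families(self):
        script = make_script("four_target", transitions_s=(0.2, 0.2, 0.2))
        rec, _ = simulate_gaze(script, 40.0, OculomotorParams(seed=1))
        stim = script_to_stimulus_signal(script, 40.0)
        disp = rc_sweep("idt", "D_T", 1.0, 0.5, 0.5, range(1, 5), rec, stim,
                        fixed={"dur_T": 100.0})
        dur = rc_sweep("idt", "dur_T", 50.0, 0.5, 50.0, range(1, 5), rec, stim,
                       fixed={"D_T": 3.0})
        assert len(disp.table) == len(dur.table) == 4


class TestEventF1:
    def test_perfect_prediction_f1_one(self):
        truth = ["fixation"] * 5 + ["saccade"] * 3 + ["smooth_pursuit"] * 4
        table = event_f1(truth, truth, ["fixation", "saccade", "smooth_pursuit"])
        assert np.allclose(table["f1"], 1.0)

    def test_hand_computed_confusion(self):
        truth = ["fixation", "fixation", "saccade", "saccade"]
        pred = ["fixation", "saccade", "saccade", "saccade"]
        table = event_f1(pred, truth, ["fixation", "saccade"])
        assert table.loc["fixation", "f1"] == pytest.approx(2 / 3)
        assert table.loc["saccade", "f1"] == pytest.approx(0.8)

    def test_absent_class_reported_missing(self):
        truth = ["fixation"] * 4
        pred = ["fixation"] * 4
        table = event_f1(pred, truth, ["fixation", "smooth_pursuit"])
        assert np.isnan(table.loc["smooth_pursuit", "f1"])

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(0)
        truth = rng.choice(["a", "b"], size=50).tolist()
        pred = rng.choice(["a", "b"], size=50).tolist()
        t1 = event_f1(pred, truth, ["a", "b"])
        swap = {"a": "z", "b": "w"}
        t2 = event_f1([swap[p] for p in pred], [swap[t] for t in truth], ["z", "w"])
        assert t1.loc["a", "f1"] == pytest.approx(t2.loc["z", "f1"])
        assert t1.loc["b", "f1"] == pytest.approx(t2.loc["w", "f1"])

    def test_behavioural_alphabet_supported(self):
        truth = ["stare", "move", "stare", "stare"]
        pred = ["stare", "stare", "stare", "move"]
        table = event_f1(pred, truth, ["stare", "move"])
        assert 0 <= table.loc["stare", "f1"] <= 1
        assert 0 <= table.loc["move", "f1"] <= 1


class TestLund2013Adapter:
    def test_reads_synthetic_format_fixture(self, tmp_path):
        # synthetic stand-in file in the annotation-export layout
        p = tmp_path / "lund_synthetic.csv"
        p.write_text(
            "t,x,y,label\n0,0.0,0.0,1\n2,0.1,0.0,1\n4,5.0,0.0,2\n"
            "6,5.1,0.0,4\n8,5.2,0.0,3\n10,5.2,0.1,5\n"
        )
        rec, labels = read_lund2013_csv(p)
        assert len(rec) == 6
        assert list(labels) == [
            "fixation", "fixation", "saccade", "smooth_pursuit", "pso", "blink",
        ]
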