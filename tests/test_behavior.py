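"""Tests of the trajectory rules and the synthetic generator."""

import numpy as np
import pandas as pd
import pytest

from comnet import analysis, behavior
from comnet.behavior import (CursorTrajectory, ScreenGeometry,
                             TRAJECTORY_KINDS, generate_synthetic_trajectory,
                             label_change_of_mind, response_onset_time,
                             summarize_behaviour)

GEOM = ScreenGeometry()


def manual_trajectory(points, chosen="right", offset=800.0):
    """Build a trajectory from (t, x, y) tuples ending on the chosen target."""
    t, x, y = map(np.asarray, zip(*points))
    return CursorTrajectory(trial_id=0, t=t, x=x, y=y, stimulus_offset=offset,
                            chosen_side=chosen, correct_side=chosen)


class TestChangeOfMindRule:
    def test_straight_reach(self):
        tx, ty = GEOM.target_position("right")
        pts = [(0, 960, 1000), (300, 960, 1000), (900, 1200, 700),
               (1100, 1500, 400), (1300, tx, ty)]
        lab = label_change_of_mind(manual_trajectory(pts))
        assert not lab.is_com and lab.n_com == 0

    def test_opposite_excursion_above_band(self):
        # 150 px beyond the centre line toward the unchosen (left) side,
        # at mid-screen height, then a reach to the right target
        tx, ty = GEOM.target_position("right")
        pts = [(0, 960, 1000), (850, 900, 800), (1000, 810, 500),
               (1200, 960, 450), (1400, 1300, 300), (1600, tx, ty)]
        lab = label_change_of_mind(manual_trajectory(pts))
        assert lab.is_com and lab.n_com == 1 and not lab.excluded_multi_com

    def test_excursion_within_bottom_band_ignored(self):
        # same 150 px excursion but low on the screen (bottom 10% of the
        # response area): early erratic movement, not a change-of-mind
        tx, ty = GEOM.target_position("right")
        y_low = GEOM.band_y + 5
        pts = [(0, 960, 1000), (850, 810, y_low), (1000, 820, y_low),
               (1200, 1100, 600), (1400, tx, ty)]
        lab = label_change_of_mind(manual_trajectory(pts))
        assert not lab.is_com

    def test_double_change_flagged_for_exclusion(self):
        tx, ty = GEOM.target_position("right")
        pts = [(0, 960, 1000), (850, 1150, 800), (1000, 790, 500),
               (1200, 1200, 400), (1400, tx, ty)]
        lab = label_change_of_mind(manual_trajectory(pts))
        assert lab.is_com and lab.n_com == 2 and lab.excluded_multi_com

    def test_unfinished_trajectory_rejected(self):
        pts = [(0, 960, 1000), (500, 960, 900), (800, 1000, 800)]
        with pytest.raises(ValueError, match="target"):
            label_change_of_mind(manual_trajectory(pts))

    def test_mirror_invariance(self):
        rng = np.random.default_rng(3)
        for i in range(30):
            tr = generate_synthetic_trajectory(
                TRAJECTORY_KINDS[i % 5], rng, trial_id=i, jitter_sd=2.0)
            mirrored = CursorTrajectory(
                trial_id=tr.trial_id, t=tr.t, x=2 * GEOM.centre_x - tr.x,
                y=tr.y, stimulus_offset=tr.stimulus_offset,
                chosen_side={"left": "right", "right": "left"}[tr.chosen_side],
                correct_side={"left": "right", "right": "left"}[tr.correct_side])
            a = label_change_of_mind(tr)
            b = label_change_of_mind(mirrored)
            assert (a.is_com, a.n_com) == (b.is_com, b.n_com)

    def test_upsampling_never_flips_labels(self):
        rng = np.random.default_rng(4)
        for i in range(30):
            tr = generate_synthetic_trajectory(
                TRAJECTORY_KINDS[i % 5], rng, trial_id=i, jitter_sd=0.0)
            t2 = np.union1d(tr.t, (tr.t[:-1] + tr.t[1:]) / 2)
            up = CursorTrajectory(
                trial_id=tr.trial_id, t=t2,
                x=np.interp(t2, tr.t, tr.x), y=np.interp(t2, tr.t, tr.y),
                stimulus_offset=tr.stimulus_offset,
                chosen_side=tr.chosen_side, correct_side=tr.correct_side)
            a, b = label_change_of_mind(tr), label_change_of_mind(up)
            assert (a.is_com, a.n_com) == (b.is_com, b.n_com)


class TestResponseOnset:
    def test_positive_response_time(self):
        # stationary until 200 ms after offset, then a 300 px reach
        pts = ([(t, 960.0, 1000.0) for t in np.arange(0, 1001, 10)]
               + [(1000 + k * 10, 960 + 15.0 * k, 1000 - 15.0 * k)
                  for k in range(1, 21)])
        onset, rt = response_onset_time(manual_trajectory(pts))
        assert onset == 1000.0 and rt == 200.0

    def test_negative_response_time(self):
        pts = ([(t, 960.0, 1000.0) for t in np.linspace(0, 700, 43)]
               + [(700 + k * 10, 960 + 12.0 * k, 1000 - 12.0 * k)
                  for k in range(1, 31)])
        onset, rt = response_onset_time(manual_trajectory(pts))
        assert rt == pytest.approx(-100.0, abs=1e-9)

    def test_tremor_does_not_set_onset(self):
        still = [(t, 960.0, 1000.0) for t in np.arange(0, 301, 10)]
        tremor = [(300 + k * 10, 960 + 8 * np.sin(k), 1000.0)
                  for k in range(1, 11)]
        still2 = [(400 + t, 960.0, 1000.0) for t in np.arange(10, 501, 10)]
        reach = [(900 + k * 10, 960 + 20.0 * k, 1000 - 20.0 * k)
                 for k in range(1, 16)]
        onset, rt = response_onset_time(
            manual_trajectory(still + tremor + still2 + reach))
        assert onset == 900.0 and rt == 100.0

    def test_no_movement_rejected(self):
        pts = [(t, 960.0, 1000.0) for t in np.arange(0, 1001, 10)]
        with pytest.raises(ValueError):
            response_onset_time(manual_trajectory(pts))


class TestSyntheticGenerator:
    def test_noise_free_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        for i in range(200):
            tr = generate_synthetic_trajectory(
                TRAJECTORY_KINDS[i % 5], rng, trial_id=i, jitter_sd=0.0)
            lab = label_change_of_mind(tr)
            onset, rt = response_onset_time(tr)
            truth = tr.ground_truth
            assert (lab.is_com, lab.n_com) == (truth.is_com, truth.n_com)
            assert onset == pytest.approx(truth.response_onset_time)
            assert rt == pytest.approx(truth.response_time)

    def test_label_recovery_under_jitter(self):
        rng = np.random.default_rng(1)
        hits = 0
        n = 300
        for i in range(n):
            tr = generate_synthetic_trajectory(
                TRAJECTORY_KINDS[i % 5], rng, trial_id=i, jitter_sd=5.0)
            lab = label_change_of_mind(tr)
            hits += (lab.is_com, lab.n_com) == (tr.ground_truth.is_com,
                                                tr.ground_truth.n_com)
        assert hits / n >= 0.99

    def test_sampling_rate_switch(self):
        rng = np.random.default_rng(2)
        tr = generate_synthetic_trajectory("direct", rng)
        dt_pre = np.diff(tr.t[tr.t < tr.stimulus_offset])
        post = tr.t[tr.t >= tr.stimulus_offset]
        assert dt_pre == pytest.approx(1000 / 60)
        assert np.diff(post) == pytest.approx(10.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_trajectory("zigzag", np.random.default_rng(0))


class TestSummaries:
    def test_com_proportion(self):
        trials = pd.DataFrame({
            "coherence": [0.0] * 970 + [0.5] * 30,
            "chosen_side": "left", "correct_side": "left",
            "is_com": [False] * 970 + [True] * 30,
            "n_com": [0] * 970 + [1] * 30,
            "response_time": 100.0,
        })
        out = summarize_behaviour(trials)
        assert out["com_overall"] == pytest.approx(0.03)

    def test_hand_tallied_per_coherence(self):
        trials = pd.DataFrame({
            "coherence": [0.0] * 20 + [0.5] * 10,
            "chosen_side": ["left"] * 25 + ["right"] * 5,
            "correct_side": "left",
            "is_com": [True] * 4 + [False] * 16 + [True] * 1 + [False] * 9,
            "n_com": [1] * 4 + [0] * 16 + [1] * 1 + [0] * 9,
            "response_time": 50.0,
        })
        out = summarize_behaviour(trials)["com_probability"]
        assert out[out.coherence == 0.0]["mean"].item() == pytest.approx(0.2)
        assert out[out.coherence == 0.5]["mean"].item() == pytest.approx(0.1)

    def test_schema_matches_simulation_analysis(self, experiment_table):
        trials = pd.DataFrame({
            "coherence": [0.0, 0.0, 0.5, 0.5], "chosen_side": "left",
            "correct_side": "left", "is_com": [True, False, False, False],
            "n_com": [1, 0, 0, 0], "response_time": 10.0,
        })
        out = summarize_behaviour(trials)
        sim_com = analysis.com_probability_by(experiment_table, "coherence")
        sim_acc = analysis.psychometric_by_com(experiment_table)
        assert list(out["com_probability"].columns) == list(sim_com.columns)
        assert list(out["accuracy"].columns) == list(sim_acc.columns)


def test_trajectory_file_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    trajs = [generate_synthetic_trajectory("com", rng, trial_id=i)
             for i in range(3)]
    path = tmp_path / "traj.csv"
    behavior.write_trajectories(trajs, path)
    back = behavior.read_trajectories(path)
    assert len(back) == 3
    for a, b in zip(trajs, back):
        assert np.allclose(a.x, b.x) and np.allclose(a.t, b.t)
        assert a.chosen_side == b.chosen_side

    bad = pd.read_csv(path).drop(columns=["y_px"])
    bad_path = tmp_path / "bad.csv"
    bad.to_csv(bad_path, index=False)
    with pytest.raises(ValueError, match="y_px"):
        behavior.read_trajectories(bad_path)


def test_timestamps_must_increase():
    with pytest.raises(ValueError, match="increasing"):
        CursorTrajectory(trial_id=0, t=[0.0, 10.0, 10.0], x=[0, 1, 2],
                         y=[0, 1, 2], stimulus_offset=800.0,
                         chosen_side="left", correct_side="left")
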