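"""Linearization, speed, performance scoring and trajectory segmentation."""

import numpy as np
import pytest

from swmaze import (compute_speed, generate_session, linearize,
                    score_performance, segment_trajectories,
                    track_from_session)
from swmaze.behavior import (LinearizedTrack, default_landmarks,
                             embed_positions)
from swmaze.core import MazeGeometry, SessionConfig, TrialRecord


def make_track(t, d):
    tr = LinearizedTrack(np.asarray(t, float), np.asarray(d, float),
                         np.full(len(t), "stem", dtype="U10"),
                         np.ones(len(t), bool))
    tr.speed = compute_speed(tr)
    return tr


class TestLinearize:
    def test_landmark_points(self):
        geom = MazeGeometry()
        lm = default_landmarks(geom)
        pts = np.array([lm["junction"], lm["start"], lm["left_end"],
                        lm["right_end"], lm["start"] - [0.0, 8.0]])
        track = linearize(pts, np.arange(5.0), geom)
        assert track.d[0] == pytest.approx(40.0)
        assert track.arm[0] == "stem"  # junction belongs to the stem range
        assert track.d[1] == pytest.approx(0.0)
        assert track.d[2] == pytest.approx(80.0)
        assert track.arm[2] == "left_goal"
        assert track.d[3] == pytest.approx(80.0)
        assert track.arm[3] == "right_goal"
        assert track.d[4] == pytest.approx(-8.0)
        assert track.arm[4] == "startbox"

    def test_round_trip_through_2d_embedding(self, standard_session):
        """Generated linear positions embedded into 2-D and re-linearized
        agree with the originals to < 0.5 cm."""
        s = standard_session
        xy = embed_positions(s)
        track = linearize(xy, s.pos_t, s.geometry)
        # the start-box <-> stem boundary is a single shared point; compare d
        assert np.max(np.abs(track.d - s.pos_d)) < 0.5
        assert track.valid.all()

    def test_off_track_samples_flagged(self):
        geom = MazeGeometry()
        pts = np.array([[0.0, 20.0], [30.0, 0.0]])  # on stem; 30 cm off track
        track = linearize(pts, np.arange(2.0), geom)
        assert track.valid[0] and not track.valid[1]


class TestSpeed:
    def test_constant_velocity(self):
        t = np.arange(0, 2, 0.04)
        track = make_track(t, 2.0 * np.arange(len(t)))  # 2 cm per 40 ms
        assert np.allclose(track.speed, 50.0)

    def test_stationary_and_direction_reversal(self):
        t = np.arange(0, 4, 0.04)
        track = make_track(t, np.zeros(len(t)))
        assert np.allclose(track.speed, 0.0)
        d = np.concatenate([np.linspace(0, 40, 50), np.linspace(40, 0, 50)])
        track = make_track(np.arange(100) * 0.04, d)
        assert np.all(track.speed >= 0)  # unsigned on inbound runs too

    def test_nonmonotone_timestamps_rejected(self):
        with pytest.raises(ValueError):
            make_track([0.0, 0.2, 0.1], [0.0, 1.0, 2.0])

    def test_recovers_planted_speed(self):
        cfg = SessionConfig(n_trials=4, seed=21, mean_speed=30.0,
                            speed_jitter=0.0, include_lfp=False)
        s = generate_session(cfg)
        track = track_from_session(s)
        segs = [x for x in segment_trajectories(s, track) if x.kind == "outbound"]
        m = (track.t >= segs[0].t_start) & (track.t < segs[0].t_end)
        assert np.median(track.speed[m]) == pytest.approx(30.0, rel=0.05)


class TestPerformance:
    @staticmethod
    def trial(i, correct, light):
        return TrialRecord(i, "L", "R" if correct else "L", light, {})

    def test_arithmetic(self):
        trials = ([self.trial(i, True, False) for i in range(20)]
                  + [self.trial(20 + i, i < 15, True) for i in range(20)])
        perf = score_performance(trials)
        assert perf.percent("off") == 100.0
        assert perf.percent("on") == 75.0
        assert perf.difference_score == 25.0
        counts = sum(v["n_trials"] for v in perf.by_condition.values())
        assert counts == len(trials)

    def test_all_incorrect_and_missing_condition(self):
        trials = [self.trial(i, False, i % 2 == 0) for i in range(10)]
        perf = score_performance(trials)
        assert perf.percent("off") == 0.0 and perf.percent("on") == 0.0
        assert perf.difference_score == 0.0
        only_off = [self.trial(i, True, False) for i in range(5)]
        perf2 = score_performance(only_off)
        assert perf2.percent("on") is None  # absent entry, not 0%
        assert perf2.difference_score is None
        with pytest.raises(ValueError):
            score_performance([])

    def test_matches_direct_recount(self):
        cfg = SessionConfig(n_trials=40, p_error=0.3, seed=11, include_lfp=False)
        s = generate_session(cfg)
        perf = score_performance(s.trials)
        for cond, flag in (("off", False), ("on", True)):
            sub = [tr for tr in s.trials if tr.light_on == flag]
            expect = 100.0 * sum(tr.correct for tr in sub) / len(sub)
            assert perf.percent(cond) == pytest.approx(expect)


class TestSegmentation:
    def test_partition_and_structure(self, standard_session, standard_track,
                                      standard_segments):
        s = standard_session
        by_key = {}
        for seg in standard_segments:
            by_key.setdefault((seg.trial, seg.phase, seg.kind), []).append(seg)
        for tr in s.trials:
            for phase in ("sample", "choice"):
                assert len(by_key[(tr.index, phase, "outbound")]) == 1
                assert len(by_key[(tr.index, phase, "inbound")]) == 1
                lo, hi = tr.phase_bounds[phase]
                segs = sorted((x for x in standard_segments
                               if x.trial == tr.index and x.phase == phase),
                              key=lambda x: x.t_start)
                for seg in segs:
                    assert lo <= seg.t_start <= seg.t_end <= hi
                out = by_key[(tr.index, phase, "outbound")][0]
                inb = by_key[(tr.index, phase, "inbound")][0]
                assert out.t_end <= inb.t_start

    def test_outbound_monotone(self, standard_track, standard_segments):
        for seg in standard_segments[:40]:
            if seg.kind != "outbound":
                continue
            m = (standard_track.t >= seg.t_start) & (standard_track.t < seg.t_end)
            d = standard_track.d[m]
            assert np.all(np.diff(d) > -2.0)  # non-decreasing up to jitter

    def test_planted_goal_dwell_duration(self):
        cfg = SessionConfig(n_trials=4, seed=31, goal_dwell_range=(2.0, 2.0),
                            include_lfp=False)
        s = generate_session(cfg)
        track = track_from_session(s)
        segs = [x for x in segment_trajectories(s, track) if x.kind == "at_goal"]
        assert segs
        for seg in segs:
            assert seg.duration == pytest.approx(2.0, abs=1.0 / 25.0 + 1e-6)

    def test_fast_goal_pass_has_no_at_goal(self):
        """An animal that never slows below 5 cm/s at the goal produces no
        at-goal segment (threshold rule)."""
        from swmaze.core import MazeGeometry, Session

        dt = 0.04
        out = np.arange(-8.0, 80.0, 50.0 * dt)  # 50 cm/s, no pause
        back = np.arange(80.0, -8.0, -50.0 * dt)
        d = np.concatenate([out, back, out, back, [-8.0]])
        t = np.arange(len(d)) * dt
        t_half = t[len(out) + len(back)]
        trial = TrialRecord(0, "L", "R", False,
                            {"sample": (0.0, t_half),
                             "delay": (t_half, t_half + 1e-3),
                             "choice": (t_half + 1e-3, t[-1] + dt)})
        s = Session(MazeGeometry(), SessionConfig(seed=0), [trial], t, d,
                    np.full(len(d), "stem", dtype="U10"), {}, [])
        track = track_from_session(s)
        segs = segment_trajectories(s, track)
        kinds = {x.kind for x in segs}
        assert "outbound" in kinds and "inbound" in kinds
        assert "at_goal" not in kinds
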