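"""Behavioral analysis: position linearization, running speed, trajectory
segmentation and working-memory performance summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .core import (
    ARM_LEFT,
    ARM_RIGHT,
    ARM_STARTBOX,
    ARM_STEM,
    MazeGeometry,
    Session,
    TrialRecord,
)

__all__ = [
    "LinearizedTrack",
    "TrajectorySegment",
    "PerformanceSummary",
    "default_landmarks",
    "embed_positions",
    "linearize",
    "track_from_session",
    "compute_speed",
    "score_performance",
    "segment_trajectories",
]

SPEED_THRESHOLD = 5.0  # cm/s, running-epoch inclusion threshold
GOAL_RADIUS = 5.0  # cm, "at goal" distance criterion


@dataclass
class LinearizedTrack:
    """Per-sample linearized position with validity and speed.

    ``d`` is distance (cm) from the stem start; ``arm`` labels start box,
    stem, or the left/right goal arm; ``valid`` marks samples close enough to
    the track (off-track samples are excluded from occupancy and spike
    assignment alike).
    """

    t: np.ndarray
    d: np.ndarray
    arm: np.ndarray
    valid: np.ndarray
    speed: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def direction(self, threshold: float = SPEED_THRESHOLD) -> np.ndarray:
        """Per-sample direction label from signed velocity."""
        v = np.gradient(self.d, self.t)
        out = np.full(len(self.t), "stationary", dtype="U10")
        out[v > threshold] = "outbound"
        out[v < -threshold] = "inbound"
        return out

    def d_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.d)


@dataclass
class TrajectorySegment:
    trial: int
    phase: str  # sample | choice
    kind: str  # outbound | at_goal | inbound
    t_start: float
    t_end: float
    goal: str  # L | R
    light_on: bool
    complete: bool = True

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class PerformanceSummary:
    """Percent-correct per light condition plus the off-minus-on difference."""

    by_condition: dict  # "off"/"on" -> {n_trials, n_correct, percent_correct}
    difference_score: float | None

    def percent(self, condition: str) -> float | None:
        entry = self.by_condition.get(condition)
        return None if entry is None else entry["percent_correct"]


def default_landmarks(geometry: MazeGeometry) -> dict:
    """Canonical 2-D embedding: stem along +y, arms along +/-x at the junction."""
    return {
        "start": np.array([0.0, 0.0]),
        "junction": np.array([0.0, geometry.stem_length]),
        "left_end": np.array([-geometry.goal_arm_length, geometry.stem_length]),
        "right_end": np.array([geometry.goal_arm_length, geometry.stem_length]),
    }


def embed_positions(session: Session) -> np.ndarray:
    """Embed a session's linear positions into 2-D maze coordinates (n, 2)."""
    lm = default_landmarks(session.geometry)
    stem_len = session.geometry.stem_length
    d, arm = session.pos_d, session.pos_arm
    xy = np.zeros((len(d), 2))
    on_track = d <= stem_len
    xy[on_track] = lm["start"] + np.outer(d[on_track], [0.0, 1.0])
    for arm_label, end in ((ARM_LEFT, lm["left_end"]), (ARM_RIGHT, lm["right_end"])):
        m = (~on_track) & (arm == arm_label)
        axis = (end - lm["junction"]) / np.linalg.norm(end - lm["junction"])
        xy[m] = lm["junction"] + np.outer(d[m] - stem_len, axis)
    return xy


def _project(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Project points onto segment a->b; return (along, perpendicular dist)."""
    ab = b - a
    L = np.linalg.norm(ab)
    u = ab / L
    rel = points - a
    along = np.clip(rel @ u, 0.0, L)
    perp = np.linalg.norm(rel - np.outer(along, u), axis=1)
    return along, perp


def linearize(xy: np.ndarray, t: np.ndarray, geometry: MazeGeometry,
              landmarks: dict | None = None, gate_cm: float = 10.0) -> LinearizedTrack:
    """Project 2-D positions onto the linearized T-maze track.

    Each sample is assigned to the nearest track segment (start box, stem,
    left or right goal arm); both goal arms map onto the same 40-80 cm range,
    with goal identity kept in the arm label.  Samples farther than
    ``gate_cm`` from every segment are flagged invalid.
    """
    if landmarks is None:
        landmarks = default_landmarks(geometry)
    xy = np.asarray(xy, float)
    start, junction = landmarks["start"], landmarks["junction"]
    stem_axis = (junction - start) / np.linalg.norm(junction - start)
    box_end = start - stem_axis * geometry.start_box_extent

    candidates = []  # (d, perp, arm)
    along, perp = _project(xy, start, junction)
    candidates.append((along, perp, ARM_STEM))
    along, perp = _project(xy, start, box_end)
    candidates.append((-along, perp, ARM_STARTBOX))
    for key, arm in (("left_end", ARM_LEFT), ("right_end", ARM_RIGHT)):
        along, perp = _project(xy, junction, landmarks[key])
        candidates.append((geometry.stem_length + along, perp, arm))

    perps = np.stack([c[1] for c in candidates])
    best = np.argmin(perps, axis=0)
    d = np.choose(best, [c[0] for c in candidates])
    arm = np.array([candidates[i][2] for i in best], dtype="U10")
    # boundary conventions: d <= stem_length is stem (junction itself is stem),
    # d < 0 is start box
    arm[(d >= 0) & (d <= geometry.stem_length) & (arm != ARM_STARTBOX)] = ARM_STEM
    arm[d < 0] = ARM_STARTBOX
    valid = perps[best, np.arange(len(d))] <= gate_cm
    track = LinearizedTrack(np.asarray(t, float), d, arm, valid,
                            provenance={"gate_cm": gate_cm})
    track.speed = compute_speed(track)
    return track


def track_from_session(session: Session) -> LinearizedTrack:
    """LinearizedTrack straight from a session's stored linear positions."""
    track = LinearizedTrack(session.pos_t, session.pos_d, session.pos_arm,
                            np.ones(len(session.pos_t), bool))
    track.speed = compute_speed(track)
    return track


def compute_speed(track: LinearizedTrack, median_filter: bool = True) -> np.ndarray:
    """Unsigned running speed |delta d| / delta t (cm/s).

    The first sample copies the second; an optional 3-sample median filter
    suppresses single-sample tracking glitches (recorded in provenance).
    """
    t, d = track.t, track.d
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    speed = np.empty(len(t))
    speed[1:] = np.abs(np.diff(d)) / dt
    speed[0] = speed[1]
    if median_filter and len(speed) >= 3:
        speed = medfilt(speed, 3)
        speed[0], speed[-1] = speed[1], speed[-2]  # shrink window at edges
    track.provenance["speed_median_filter"] = median_filter
    return speed


def score_performance(trials: list[TrialRecord]) -> PerformanceSummary:
    """Percent correct in light-off and light-on trials and their difference."""
    if not trials:
        raise ValueError("no trials to score")
    by_condition = {}
    for cond, flag in (("off", False), ("on", True)):
        sub = [tr for tr in trials if tr.light_on == flag]
        if not sub:
            continue
        n_corr = sum(tr.correct for tr in sub)
        by_condition[cond] = {
            "n_trials": len(sub),
            "n_correct": n_corr,
            "percent_correct": 100.0 * n_corr / len(sub),
        }
    diff = None
    if "off" in by_condition and "on" in by_condition:
        diff = (by_condition["off"]["percent_correct"]
                - by_condition["on"]["percent_correct"])
    return PerformanceSummary(by_condition, diff)


def segment_trajectories(session: Session, track: LinearizedTrack,
                         speed_threshold: float = SPEED_THRESHOLD,
                         goal_radius: float = GOAL_RADIUS) -> list[TrajectorySegment]:
    """Split each sample/choice phase into outbound, at-goal and inbound parts.

    Outbound runs from start-box exit (d crossing 0) to goal arrival
    (first sample within ``goal_radius`` of the goal); at-goal epochs require
    speed <= ``speed_threshold`` and distance-to-goal <= ``goal_radius``;
    inbound runs from goal departure back to start-box entry.  Phases where
    the animal never reaches the goal yield an incomplete outbound segment
    that downstream analyses exclude.
    """
    d_goal = session.geometry.goal_position
    speed = track.speed if track.speed is not None else compute_speed(track)
    segments: list[TrajectorySegment] = []
    for tr in session.trials:
        for phase in ("sample", "choice"):
            if phase not in tr.phase_bounds:
                continue
            lo, hi = tr.phase_bounds[phase]
            idx = np.flatnonzero((track.t >= lo) & (track.t < hi))
            if len(idx) == 0:
                continue
            t, d, v = track.t[idx], track.d[idx], speed[idx]
            goal = tr.goal_for(phase)
            exit_i = np.flatnonzero(d >= 0)
            near_goal = d >= d_goal - goal_radius
            arrive_i = np.flatnonzero(near_goal)
            if len(exit_i) == 0:
                continue
            if len(arrive_i) == 0:  # never reached the goal
                segments.append(TrajectorySegment(
                    tr.index, phase, "outbound", t[exit_i[0]], t[-1], goal,
                    tr.light_on, complete=False))
                continue
            i_out0, i_arrive = exit_i[0], arrive_i[0]
            segments.append(TrajectorySegment(
                tr.index, phase, "outbound", t[i_out0], t[i_arrive], goal,
                tr.light_on))
            i_depart = arrive_i[-1]
            at_goal = near_goal & (v <= speed_threshold)
            at_goal[:i_arrive] = False
            if np.any(at_goal):
                edges = np.diff(at_goal.astype(int))
                starts = list(np.flatnonzero(edges == 1) + 1)
                ends = list(np.flatnonzero(edges == -1) + 1)
                if at_goal[0]:
                    starts.insert(0, 0)
                if at_goal[-1]:
                    ends.append(len(at_goal))
                for s, e in zip(starts, ends):
                    segments.append(TrajectorySegment(
                        tr.index, phase, "at_goal", t[s],
                        t[e - 1] + (t[1] - t[0] if len(t) > 1 else 0.0),
                        goal, tr.light_on))
            back_i = np.flatnonzero(d[i_depart:] <= 0)
            i_home = (i_depart + back_i[0]) if len(back_i) else len(t) - 1
            segments.append(TrajectorySegment(
                tr.index, phase, "inbound", t[i_depart], t[i_home], goal,
                tr.light_on))
    return segments


def segments_table(segments: list[TrajectorySegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.trial, s.phase, s.kind, s.t_start, s.t_end, s.goal, s.light_on,
          s.complete) for s in segments],
        columns=["trial", "phase", "kind", "t_start", "t_end", "goal",
                 "light_on", "complete"])
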