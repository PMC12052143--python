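"""Position-resolved decoding of the visited goal arm from population
activity vectors, via paired-resampling cross-validation around a linear
max-margin classifier.

For each position bin, goal activity vectors (one per trial, one entry per
unit) are built from side-separated rates; per repeat, random left/right
trial pairs are drawn and a leave-one-pair-out cross-validation of a
standardized linear SVM yields a per-bin accuracy, averaged over folds and
repeats.  Chance is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .behavior import LinearizedTrack, TrajectorySegment
from .core import LEFT, RIGHT, Session
from .goal_coding import goal_arm_rates

__all__ = ["GoalVectors", "GoalDecodingResult", "build_goal_vectors",
           "decode_goal_by_position"]

MIN_UNITS = 15
MIN_RATE_HZ = 0.5
N_PAIRS = {"sample": 10, "choice": 8}
N_REPEATS = 100


@dataclass
class GoalVectors:
    """Per-bin labeled activity vectors: bins x trials x units."""

    status: str  # "ok" | "excluded"
    position_labels: list[str] = field(default_factory=list)
    vectors: np.ndarray | None = None  # (n_bins, n_trials, n_units)
    labels: np.ndarray | None = None  # (n_trials,) "L"/"R"
    units: list[str] = field(default_factory=list)
    detail: dict = field(default_factory=dict)


def _mean_rate_in_phase(spikes: np.ndarray, segments) -> float:
    total_t = sum(s.duration for s in segments)
    if total_t <= 0:
        return 0.0
    n = sum(int(np.sum((spikes >= s.t_start) & (spikes < s.t_end)))
            for s in segments)
    return n / total_t


def build_goal_vectors(session: Session, track: LinearizedTrack,
                       segments: list[TrajectorySegment], phase: str,
                       light_on: bool, min_units: int = MIN_UNITS,
                       min_rate_hz: float = MIN_RATE_HZ) -> GoalVectors:
    """Goal activity vectors for every unfolded position bin.

    Units must average > ``min_rate_hz`` over the phase to join the roster;
    sessions with <= ``min_units`` qualifying units are excluded.  Vector
    entries are per-trial rates in the bin; bins a trial never occupied
    contribute 0 (no spikes observed there).
    """
    phase_segs = [s for s in segments if s.phase == phase]
    roster = [u for u in session.units
              if _mean_rate_in_phase(session.spikes[u], phase_segs) > min_rate_hz]
    if len(roster) <= min_units:
        return GoalVectors("excluded",
                           detail={"reason": f"<= {min_units} units above "
                                             f"{min_rate_hz} Hz", "n": len(roster)})
    per_unit = {u: goal_arm_rates(session.spikes[u], segments, track, phase,
                                  light_on) for u in roster}
    labels_pos = per_unit[roster[0]].position_labels
    n_bins = len(labels_pos)

    trials, labels = [], []
    for tr in session.trials:
        goal = tr.goal_for(phase)
        if tr.light_on == light_on:
            trials.append(tr.index)
            labels.append(goal)
    trials = np.array(trials)
    labels = np.array(labels)

    vectors = np.zeros((n_bins, len(trials), len(roster)))
    for j, u in enumerate(roster):
        prof = per_unit[u]
        for side in (LEFT, RIGHT):
            if side not in prof.outbound:
                continue
            out_rm = prof.outbound[side]
            in_rm = prof.inbound[side]
            g_ids, g_rates = prof.at_goal[side]
            n_out = out_rm.n_bins
            for k, tr_id in enumerate(out_rm.trial_ids):
                col = np.flatnonzero(trials == tr_id)
                if not len(col):
                    continue
                c = col[0]
                r_out = out_rm.rate[k]
                vectors[:n_out, c, j] = np.nan_to_num(r_out)
            for k, tr_id in enumerate(in_rm.trial_ids):
                col = np.flatnonzero(trials == tr_id)
                if not len(col):
                    continue
                c = col[0]
                r_in = in_rm.rate[k][::-1]
                vectors[n_out + 1:, c, j] = np.nan_to_num(r_in)
            for tr_id, r in zip(g_ids, g_rates):
                col = np.flatnonzero(trials == tr_id)
                if len(col):
                    vectors[n_out, col[0], j] = np.nan_to_num(r)
    return GoalVectors("ok", labels_pos, vectors, labels, roster)


@dataclass
class GoalDecodingResult:
    status: str
    position_labels: list[str] = field(default_factory=list)
    percent_correct: np.ndarray | None = None  # per bin
    p_adj: np.ndarray | None = None  # Bonferroni-corrected z-test vs 50%
    above_chance: np.ndarray | None = None
    n_units: int = 0
    n_trials: int = 0
    detail: dict = field(default_factory=dict)

    def to_table(self, phase: str = "", condition: str = "") -> pd.DataFrame:
        return pd.DataFrame({"phase": phase, "condition": condition,
                             "position_label": self.position_labels,
                             "percent_correct": self.percent_correct,
                             "p_adj": self.p_adj})


def decode_goal_by_position(gv: GoalVectors, n_pairs: int,
                            n_repeats: int = N_REPEATS,
                            rng: np.random.Generator | int | None = None,
                            C: float = 1.0) -> GoalDecodingResult:
    """Paired-resampling leave-one-pair-out goal decoding per position bin.

    Per repeat, ``n_pairs`` left trials and ``n_pairs`` right trials are
    drawn without replacement and paired; each fold holds out one pair and
    trains a standardized linear SVM on the rest.  Accuracies are averaged
    over folds then repeats; per-bin significance vs 50% uses a one-
    proportion z-test on the pooled fold-level counts, Bonferroni-corrected
    over bins.
    """
    if gv.status != "ok":
        return GoalDecodingResult("excluded", detail=gv.detail)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    left_idx = np.flatnonzero(gv.labels == LEFT)
    right_idx = np.flatnonzero(gv.labels == RIGHT)
    if len(left_idx) < n_pairs or len(right_idx) < n_pairs:
        return GoalDecodingResult(
            "excluded", detail={"reason": f"fewer than {n_pairs} trials per side"})

    n_bins = gv.vectors.shape[0]
    correct = np.zeros(n_bins)
    total = np.zeros(n_bins)
    y_all = np.array([0] * n_pairs + [1] * n_pairs)
    for _ in range(n_repeats):
        L = rng.choice(left_idx, n_pairs, replace=False)
        R = rng.choice(right_idx, n_pairs, replace=False)
        sel = np.concatenate([L, R])
        for b in range(n_bins):
            X = gv.vectors[b, sel]  # (2*n_pairs, n_units)
            for fold in range(n_pairs):
                test = np.array([fold, n_pairs + fold])
                train = np.setdiff1d(np.arange(2 * n_pairs), test)
                assert not np.intersect1d(train, test).size
                clf = make_pipeline(StandardScaler(),
                                    SVC(kernel="linear", C=C))
                clf.fit(X[train], y_all[train])
                pred = clf.predict(X[test])
                correct[b] += np.sum(pred == y_all[test])
                total[b] += len(test)
    pct = 100.0 * correct / total
    phat = correct / total
    z = (phat - 0.5) / np.sqrt(0.25 / total)
    p = 2 * sps.norm.sf(np.abs(z))
    p_adj = np.clip(p * n_bins, 0, 1)
    return GoalDecodingResult("ok", gv.position_labels, pct, p_adj,
                              (p_adj < 0.05) & (phat > 0.5), len(gv.units),
                              len(gv.labels))
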