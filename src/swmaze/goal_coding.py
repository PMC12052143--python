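"""Goal-selective firing: side-separated rate profiles, the goal-selectivity
ANOVA, and the position-resolved goal index.

The goal index at a position is ``(f_pref - f_nonpref) / (f_pref + f_nonpref)``
where preferred/nonpreferred are the goal arms with overall higher/lower
firing; it lies in [-1, 1] and is undefined (NaN) when both rates are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import LinearizedTrack, TrajectorySegment
from .core import LEFT, RIGHT, SIDES, other_side
from .ratemaps import RateMap, linearized_rate_map, select_segments

__all__ = ["GoalRateProfile", "GoalSelectivity", "GoalIndexProfile",
           "goal_arm_rates", "goal_summary_bins", "goal_selectivity_test",
           "goal_index_profile", "two_way_anova"]

GOAL_BIN_WIDTH = 20.0
GOAL_BIN_OVERLAP = 10.0
GOAL_ARM_LO = 40.0  # cm; goal-arm positions span 40-80
ALPHA_GOAL = 0.025  # two-condition Bonferroni, taken verbatim


@dataclass
class GoalRateProfile:
    """Per-side, per-trial rates along the unfolded trajectory.

    For each goal side: outbound 20 cm bins (10 cm overlap), a scalar
    at-goal rate (speed <= 5 cm/s within 5 cm of the goal), and inbound bins.
    """

    outbound: dict  # side -> RateMap
    at_goal: dict  # side -> (trial_ids, rates) arrays
    inbound: dict  # side -> RateMap
    metadata: dict = field(default_factory=dict)

    @property
    def position_labels(self) -> list[str]:
        rm = self.outbound[LEFT]
        out = [f"out_{lo:.0f}-{hi:.0f}" for lo, hi in zip(rm.bin_lo, rm.bin_hi)]
        inb = [f"in_{hi:.0f}-{lo:.0f}" for lo, hi in
               zip(rm.bin_lo[::-1], rm.bin_hi[::-1])]
        return out + ["goal"] + inb

    def averaged_profile(self, side: str) -> np.ndarray:
        """Averaged rates along the unfolded axis (outbound, goal, inbound)."""
        out = self.outbound[side].avg_rate
        _, goal_rates = self.at_goal[side]
        g = np.nanmean(goal_rates) if len(goal_rates) else np.nan
        inb = self.inbound[side].avg_rate[::-1]
        return np.concatenate([out, [g], inb])


def _at_goal_rates(spikes: np.ndarray, segments: list[TrajectorySegment]):
    """Per-trial rate during pooled at-goal epochs."""
    trial_ids = sorted({s.trial for s in segments})
    rates = []
    for tr in trial_ids:
        segs = [s for s in segments if s.trial == tr]
        total_t = sum(s.duration for s in segs)
        n = sum(int(np.sum((spikes >= s.t_start) & (spikes < s.t_end)))
                for s in segs)
        rates.append(n / total_t if total_t > 0 else np.nan)
    return np.array(trial_ids), np.array(rates)


def goal_arm_rates(spikes: np.ndarray, segments: list[TrajectorySegment],
                   track: LinearizedTrack, phase: str, light_on: bool,
                   bin_width: float = GOAL_BIN_WIDTH,
                   bin_overlap: float = GOAL_BIN_OVERLAP) -> GoalRateProfile:
    """Side-separated rate profile for one phase and light condition."""
    spikes = np.asarray(spikes, float)
    outbound, at_goal, inbound = {}, {}, {}
    for side in SIDES:
        out_segs = select_segments(segments, phase=phase, light_on=light_on,
                                   kinds=("outbound",), goal=side)
        in_segs = select_segments(segments, phase=phase, light_on=light_on,
                                  kinds=("inbound",), goal=side)
        goal_segs = select_segments(segments, phase=phase, light_on=light_on,
                                    kinds=("at_goal",), goal=side)
        if not out_segs:
            continue
        outbound[side] = linearized_rate_map(
            spikes, out_segs, track, bin_width=bin_width, bin_overlap=bin_overlap)
        inbound[side] = linearized_rate_map(
            spikes, in_segs, track, bin_width=bin_width, bin_overlap=bin_overlap)
        at_goal[side] = _at_goal_rates(spikes, goal_segs)
    return GoalRateProfile(outbound, at_goal, inbound,
                           {"phase": phase, "light_on": light_on})


def goal_summary_bins(spikes: np.ndarray, segments: list[TrajectorySegment],
                      track: LinearizedTrack, phase: str, light_on: bool,
                      arm_lo: float = GOAL_ARM_LO) -> dict:
    """Per-trial three-bin summary per side.

    The three goal-arm bins are: averaged rate over goal-arm positions
    (40-80 cm) of the outbound run, the at-goal rate, and the averaged rate
    over the same positions of the inbound run.  Returns
    ``side -> (n_trials, 3)`` arrays (rows are trials with all bins defined).
    """
    spikes = np.asarray(spikes, float)
    out = {}
    for side in SIDES:
        rows = {}
        for kind, col in (("outbound", 0), ("inbound", 2)):
            segs = select_segments(segments, phase=phase, light_on=light_on,
                                   kinds=(kind,), goal=side)
            if not segs:
                break
            rm = linearized_rate_map(spikes, segs, track, bin_width=40.0,
                                     bin_overlap=0.0, d_range=(arm_lo, 80.0))
            for tr, c, o in zip(rm.trial_ids, rm.counts[:, 0], rm.occupancy[:, 0]):
                rows.setdefault(tr, [np.nan] * 3)[col] = c / o if o > 0 else np.nan
        goal_segs = select_segments(segments, phase=phase, light_on=light_on,
                                    kinds=("at_goal",), goal=side)
        trial_ids, rates = _at_goal_rates(spikes, goal_segs)
        for tr, r in zip(trial_ids, rates):
            if tr in rows:
                rows[tr][1] = r
        mat = np.array([rows[tr] for tr in sorted(rows)])
        if len(mat):
            mat = mat[~np.isnan(mat).any(axis=1)]
        out[side] = mat
    return out


def two_way_anova(values: np.ndarray, factor_a: np.ndarray,
                  factor_b: np.ndarray) -> dict:
    """Two-way crossed ANOVA with interaction (type II sums of squares).

    Small fixed design (goal x position); computed from cell means, which for
    balanced or proportional designs matches the classical decomposition.
    Returns p-values for both main effects and the interaction.
    """
    df = pd.DataFrame({"y": values, "a": factor_a, "b": factor_b})
    grand = df.y.mean()
    n = len(df)
    ss_total = ((df.y - grand) ** 2).sum()
    mean_a = df.groupby("a").y.mean()
    mean_b = df.groupby("b").y.mean()
    count_a = df.groupby("a").y.count()
    count_b = df.groupby("b").y.count()
    ss_a = float((count_a * (mean_a - grand) ** 2).sum())
    ss_b = float((count_b * (mean_b - grand) ** 2).sum())
    cell = df.groupby(["a", "b"]).y.agg(["mean", "count"])
    ss_cells = float((cell["count"] * (cell["mean"] - grand) ** 2).sum())
    ss_ab = max(ss_cells - ss_a - ss_b, 0.0)
    ss_err = max(float(ss_total) - ss_cells, 0.0)
    df_a = df.a.nunique() - 1
    df_b = df.b.nunique() - 1
    df_ab = df_a * df_b
    df_err = n - df.a.nunique() * df.b.nunique()
    out = {}
    for name, ss, dfx in (("a", ss_a, df_a), ("b", ss_b, df_b),
                          ("ab", ss_ab, df_ab)):
        if df_err <= 0 or ss_err <= 1e-300:
            out[f"p_{name}"] = 0.0 if ss > 1e-300 else 1.0
            out[f"F_{name}"] = np.inf if ss > 1e-300 else 0.0
            continue
        F = (ss / dfx) / (ss_err / df_err) if dfx > 0 else np.nan
        out[f"F_{name}"] = float(F)
        out[f"p_{name}"] = float(sps.f.sf(F, dfx, df_err))
    return out


@dataclass
class GoalSelectivity:
    significant: bool
    p_by_condition: dict  # "off"/"on" -> p_goal (NaN if untestable)
    preferred: str | None
    condition: str | None  # off | on | both | None


def goal_selectivity_test(summaries_by_condition: dict,
                          alpha: float = ALPHA_GOAL) -> GoalSelectivity:
    """Goal-selectivity from the goal x position ANOVA on the 3 summary bins.

    ``summaries_by_condition`` maps "off"/"on" to the per-side (n_trials, 3)
    arrays from :func:`goal_summary_bins`.  A unit is goal-selective when the
    main effect of goal is significant (p < 0.025) in either light condition;
    the preferred goal is the side with the overall higher mean rate in
    light-off trials.
    """
    p_by = {}
    for cond, summaries in summaries_by_condition.items():
        L, R = summaries.get(LEFT), summaries.get(RIGHT)
        if L is None or R is None or len(L) < 2 or len(R) < 2:
            p_by[cond] = np.nan
            continue
        vals = np.concatenate([L.ravel(), R.ravel()])
        goal = np.array([LEFT] * L.size + [RIGHT] * R.size)
        pos = np.concatenate([np.tile([0, 1, 2], len(L)),
                              np.tile([0, 1, 2], len(R))])
        p_by[cond] = two_way_anova(vals, goal, pos)["p_a"]
    sig_conds = [c for c, p in p_by.items() if np.isfinite(p) and p < alpha]
    significant = bool(sig_conds)
    preferred = None
    if significant:
        ref = summaries_by_condition.get("off") or next(iter(
            summaries_by_condition.values()))
        means = {s: np.nanmean(ref[s]) for s in SIDES if s in ref and len(ref[s])}
        if means:
            preferred = max(means, key=means.get)
    condition = None
    if sig_conds:
        condition = "both" if len(sig_conds) == 2 else sig_conds[0]
    return GoalSelectivity(significant, p_by, preferred, condition)


@dataclass
class GoalIndexProfile:
    position_labels: list[str]
    index: np.ndarray  # per position, in [-1, 1]; NaN where both rates are 0
    preferred: str

    def to_table(self, unit: str = "", condition: str = "") -> pd.DataFrame:
        return pd.DataFrame({"unit": unit, "condition": condition,
                             "position_label": self.position_labels,
                             "goal_index": self.index})


def goal_index_profile(profile: GoalRateProfile, preferred: str) -> GoalIndexProfile:
    """Goal index per unfolded position for one condition.

    The axis concatenates outbound bins, the at-goal point and inbound bins
    in traversal order.
    """
    if preferred not in SIDES:
        raise ValueError("preferred must be 'L' or 'R'")
    f_pref = profile.averaged_profile(preferred)
    f_non = profile.averaged_profile(other_side(preferred))
    num = f_pref - f_non
    den = f_pref + f_non
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(den > 0, num / den, np.nan)
    return GoalIndexProfile(profile.position_labels, idx, preferred)
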