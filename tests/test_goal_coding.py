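"""Goal-selective firing: side-separated rates, the selectivity ANOVA and
the goal index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swmaze import generate_session, segment_trajectories, track_from_session
from swmaze.core import NeuronSpec, SessionConfig
from swmaze.goal_coding import (GoalRateProfile, goal_arm_rates,
                                goal_index_profile, goal_selectivity_test,
                                goal_summary_bins, two_way_anova)
from swmaze.ratemaps import RateMap


def goal_session(gain, seed, n_trials=40, baseline=4.0, preferred="L"):
    neurons = [NeuronSpec(baseline_rate=baseline, goal_gain=gain,
                          preferred_goal=preferred)]
    cfg = SessionConfig(n_trials=n_trials, seed=seed, include_lfp=False)
    s = generate_session(cfg, neurons=neurons)
    track = track_from_session(s)
    return s, track, segment_trajectories(s, track)


class TestGoalArmRates:
    def test_at_goal_rate_definition(self, standard_session, standard_track,
                                     standard_segments):
        """At-goal rate equals spikes / dwell time recounted directly."""
        s = standard_session
        u = s.units[0]
        prof = goal_arm_rates(s.spikes[u], standard_segments, standard_track,
                              "sample", False)
        for side, (trial_ids, rates) in prof.at_goal.items():
            segs = [x for x in standard_segments
                    if x.kind == "at_goal" and x.phase == "sample"
                    and not x.light_on and x.goal == side
                    and x.trial == trial_ids[0]]
            t_total = sum(x.duration for x in segs)
            n = sum(np.sum((s.spikes[u] >= x.t_start) & (s.spikes[u] < x.t_end))
                    for x in segs)
            assert rates[0] == pytest.approx(n / t_total)

    def test_overlapping_bin_layout(self, standard_session, standard_track,
                                    standard_segments):
        prof = goal_arm_rates(standard_session.spikes["u000"],
                              standard_segments, standard_track, "sample",
                              False)
        rm = prof.outbound["L"]
        assert np.allclose(rm.bin_lo, np.arange(0.0, 61.0, 10.0))
        assert np.allclose(rm.bin_hi - rm.bin_lo, 20.0)
        # a spike at d = 55 cm falls in bins [40,60) and [50,70)
        assert rm.bin_lo[4] == 40.0 and rm.bin_lo[5] == 50.0

    def test_planted_gain_recovered_in_rate_ratio(self):
        """goal_gain = 2 on the left arm doubles left vs right arm rates."""
        s, track, segs = goal_session(2.0, seed=23, n_trials=100)
        prof = goal_arm_rates(s.spikes["u000"], segs, track, "sample", False)
        on_arm = prof.outbound["L"].centers >= 50.0
        left = np.nanmean(prof.outbound["L"].avg_rate[on_arm])
        right = np.nanmean(prof.outbound["R"].avg_rate[on_arm])
        assert left / right == pytest.approx(2.0, rel=0.1)


class TestSelectivity:
    def test_planted_selectivity_recovered(self):
        """gain = 3, 20 trials/side: significant with the planted side
        preferred in >= 95% of seeds."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            s, track, segs = goal_session(3.0, seed=200 + seed)
            summ = {c: goal_summary_bins(s.spikes["u000"], segs, track,
                                         "sample", f)
                    for c, f in (("off", False), ("on", True))}
            sel = goal_selectivity_test(summ)
            hits += sel.significant and sel.preferred == "L"
        assert hits >= int(0.95 * n_seeds)

    def test_type_one_error_controlled(self):
        """gain = 1 (no selectivity): <= 3.5% of 500 simulated cells reach
        p < 0.025 in a given condition."""
        rng = np.random.default_rng(77)
        false_pos = 0
        n_cells = 500
        for _ in range(n_cells):
            # per-trial three-bin summaries from a constant-rate Poisson cell
            dwell = 2.0
            L = rng.poisson(8.0 * dwell, (20, 3)) / dwell
            R = rng.poisson(8.0 * dwell, (20, 3)) / dwell
            summ = {"off": {"L": L, "R": R}}
            sel = goal_selectivity_test(summ)
            p = sel.p_by_condition["off"]
            false_pos += np.isfinite(p) and p < 0.025
        assert false_pos <= 0.035 * n_cells

    def test_deterministic_equal_rates_not_selective(self):
        L = np.tile([5.0, 7.0, 3.0], (10, 1))
        sel = goal_selectivity_test({"off": {"L": L, "R": L.copy()}})
        assert not sel.significant
        assert sel.p_by_condition["off"] == pytest.approx(1.0)

    def test_two_way_anova_against_statsmodels(self):
        """Balanced goal x position table matches the statsmodels OLS ANOVA."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        y = rng.normal(5.0, 1.0, 60)
        goal = np.repeat(["L", "R"], 30)
        pos = np.tile(np.repeat([0, 1, 2], 10), 2)
        res = two_way_anova(y, goal, pos)
        df = pd.DataFrame({"y": y, "goal": goal, "pos": pos.astype(str)})
        table = sm.stats.anova_lm(ols("y ~ C(goal) * C(pos)", df).fit(), typ=2)
        assert res["p_a"] == pytest.approx(table.loc["C(goal)", "PR(>F)"],
                                           abs=1e-10)
        assert res["p_b"] == pytest.approx(table.loc["C(pos)", "PR(>F)"],
                                           abs=1e-10)

    def test_unbalanced_side_skipped(self):
        sel = goal_selectivity_test({"off": {"L": np.ones((1, 3)),
                                             "R": np.ones((5, 3))}})
        assert not sel.significant
        assert np.isnan(sel.p_by_condition["off"])


class TestGoalIndex:
    def make_profile(self, left_rates, right_rates):
        nb = 7
        lo = np.arange(0.0, 61.0, 10.0)
        hi = lo + 20.0

        def rmap(r):
            occ = np.ones((1, nb))
            return RateMap(lo, hi, np.array([0]), np.array([r]), occ)

        return GoalRateProfile(
            {"L": rmap(left_rates), "R": rmap(right_rates)},
            {"L": (np.array([0]), np.array([left_rates[-1]])),
             "R": (np.array([0]), np.array([right_rates[-1]]))},
            {"L": rmap(left_rates), "R": rmap(right_rates)})

    def test_extremes_and_arithmetic(self):
        prof = self.make_profile(np.full(7, 10.0), np.zeros(7))
        gip = goal_index_profile(prof, "L")
        assert np.allclose(gip.index, 1.0)
        prof = self.make_profile(np.full(7, 6.0), np.full(7, 2.0))
        assert np.allclose(goal_index_profile(prof, "L").index, 0.5)
        prof = self.make_profile(np.full(7, 3.0), np.full(7, 3.0))
        assert np.allclose(goal_index_profile(prof, "L").index, 0.0)

    def test_both_zero_is_missing(self):
        prof = self.make_profile(np.zeros(7), np.zeros(7))
        assert np.all(np.isnan(goal_index_profile(prof, "L").index))

    @given(c=st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(3)
        L, R = rng.uniform(1, 10, 7), rng.uniform(1, 10, 7)
        base = goal_index_profile(self.make_profile(L, R), "L").index
        scaled = goal_index_profile(self.make_profile(c * L, c * R), "L").index
        assert np.allclose(base, scaled)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        L, R = rng.uniform(1, 10, 7), rng.uniform(1, 10, 7)
        prof = self.make_profile(L, R)
        a = goal_index_profile(prof, "L").index
        b = goal_index_profile(prof, "R").index
        assert np.allclose(a, -b)

    def test_axis_order_is_traversal_order(self):
        prof = self.make_profile(np.arange(7.0) + 1, np.ones(7))
        labels = goal_index_profile(prof, "L").position_labels
        assert labels[0].startswith("out_0")
        assert labels[7] == "goal"
        assert labels[8].startswith("in_80")
        assert len(labels) == 15
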