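"""Rate maps, the position RM-ANOVA, spatial information and map
correlations, each checked against independent closed-form or brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from swmaze import (generate_session, segment_trajectories,
                    track_from_session)
from swmaze.core import NeuronSpec, SessionConfig, gaussian_field
from swmaze.ratemaps import (RateMap, linearized_rate_map, map_correlation,
                             select_segments, smooth_map,
                             spatial_information, spatial_modulation_test,
                             split_half_correlation)


def make_ratemap(counts, occupancy, lo=None, hi=None):
    counts = np.atleast_2d(np.asarray(counts, float))
    occupancy = np.atleast_2d(np.asarray(occupancy, float))
    nb = counts.shape[1]
    if lo is None:
        lo = np.arange(nb) * 10.0
        hi = lo + 10.0
    return RateMap(lo, hi, np.arange(counts.shape[0]), counts, occupancy)


class TestRateMap:
    def test_rate_is_count_over_occupancy(self):
        rm = make_ratemap([[5, 0]], [[0.5, 1.0]])
        assert rm.rate[0, 0] == 10.0  # 5 spikes in 0.5 s -> 10 Hz
        assert rm.avg_rate[1] == 0.0

    def test_zero_occupancy_bin_is_missing(self):
        rm = make_ratemap([[5, 0]], [[0.5, 0.0]])
        assert np.isnan(rm.rate[0, 1]) and np.isnan(rm.avg_rate[1])

    def test_speed_filter_can_empty_the_map(self, standard_session,
                                            standard_track, standard_segments):
        segs = select_segments(standard_segments, phase="sample",
                               kinds=("outbound",))[:4]
        with pytest.raises(ValueError):
            linearized_rate_map(standard_session.spikes["u000"], segs,
                                standard_track, speed_min=1e6)

    def test_peak_recovers_planted_field_center(self):
        spec = [NeuronSpec(baseline_rate=0.2,
                           tuning=gaussian_field(55.0, 6.0, 18.0))]
        s = generate_session(SessionConfig(n_trials=100, seed=17,
                                           include_lfp=False), neurons=spec)
        track = track_from_session(s)
        segs = select_segments(segment_trajectories(s, track),
                               phase=None, kinds=("outbound",))
        rm = linearized_rate_map(s.spikes["u000"], segs, track)
        peak_center = rm.centers[np.nanargmax(rm.avg_rate)]
        assert abs(peak_center - 55.0) <= 10.0  # within one bin

    def test_overlapping_bins_share_samples(self, standard_session,
                                            standard_track, standard_segments):
        segs = select_segments(standard_segments, phase="sample",
                               light_on=False)
        u = standard_session.spikes["u010"]
        rm = linearized_rate_map(u, segs, standard_track, bin_width=20.0,
                                 bin_overlap=10.0)
        # a spike at d in [50, 60) must appear in both bins [40,60) and [50,70)
        assert rm.bin_lo[4] == 40.0 and rm.bin_lo[5] == 50.0
        total_narrow = linearized_rate_map(u, segs, standard_track,
                                           bin_width=10.0).counts.sum()
        # with 10 cm overlap every interior spike is counted twice
        assert rm.counts.sum() >= total_narrow


class TestSpatialANOVA:
    def test_matches_hand_sum_of_squares(self):
        """3 trials x 4 bins table against an explicit SS decomposition."""
        x = np.array([[2.0, 5.0, 9.0, 4.0],
                      [3.0, 6.0, 7.0, 5.0],
                      [1.0, 7.0, 8.0, 3.0]])
        rm = make_ratemap(x, np.ones_like(x))
        res = spatial_modulation_test(rm)
        grand = x.mean()
        ss_pos = 3 * sum((x[:, b].mean() - grand) ** 2 for b in range(4))
        ss_tr = 4 * sum((x[r].mean() - grand) ** 2 for r in range(3))
        ss_tot = ((x - grand) ** 2).sum()
        ss_err = ss_tot - ss_pos - ss_tr
        F = (ss_pos / 3) / (ss_err / 6)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(sps.f.sf(F, 3, 6), rel=1e-12)

    def test_degenerate_tables(self):
        x = np.tile([1.0, 5.0, 9.0], (3, 1))  # identical trials
        res = spatial_modulation_test(make_ratemap(x, np.ones_like(x)))
        assert res.significant and res.p == 0.0
        flat = np.ones((4, 5)) * 3.0
        res2 = spatial_modulation_test(make_ratemap(flat, np.ones_like(flat)))
        assert res2.F == 0.0 and res2.p == 1.0 and not res2.significant

    def test_incomplete_trials_dropped(self):
        x = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0]])
        occ = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])  # trial 1 missing
        res = spatial_modulation_test(make_ratemap(x, occ))
        assert res.n_trials == 2


class TestSpatialInformation:
    def test_uniform_map_is_zero_bits(self):
        assert spatial_information(np.full(8, 7.0), np.ones(8)) == pytest.approx(0.0)

    def test_single_bin_firing_closed_form(self):
        rates = np.zeros(8)
        rates[3] = 16.0
        # all spikes in 1 of 8 equally occupied bins -> log2(8) = 3 bits/spike
        assert spatial_information(rates, np.ones(8)) == pytest.approx(3.0)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(5)
        rates = rng.uniform(0, 20, 12)
        occ = rng.uniform(0.1, 2.0, 12)
        p = occ / occ.sum()
        f = (p * rates).sum()
        si_oracle = sum(p[i] * (rates[i] / f) * np.log2(rates[i] / f)
                        for i in range(12) if rates[i] > 0)
        assert spatial_information(rates, occ) == pytest.approx(si_oracle,
                                                                abs=1e-12)

    def test_silent_cell_undefined(self):
        with pytest.raises(ValueError):
            spatial_information(np.zeros(8), np.ones(8))

    @given(scale=st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_to_global_rate_scaling(self, scale):
        rng = np.random.default_rng(7)
        rates = rng.uniform(0.1, 10.0, 10)
        occ = rng.uniform(0.5, 2.0, 10)
        si = spatial_information(rates, occ)
        assert spatial_information(rates * scale, occ) == pytest.approx(si)

    def test_zero_occupancy_bin_ignored(self):
        rates = np.array([2.0, 8.0, 4.0])
        occ = np.array([1.0, 1.0, 1.0])
        si = spatial_information(rates, occ)
        rates2 = np.append(rates, 100.0)
        occ2 = np.append(occ, 0.0)
        assert spatial_information(rates2, occ2) == pytest.approx(si)


class TestMapCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 10, 30)
        assert map_correlation(m, m) == pytest.approx(1.0)
        assert map_correlation(m, 2 * m.mean() - m) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        shared = np.exp(-0.5 * ((np.arange(40) - 20) / 5.0) ** 2) * 10
        a = shared + rng.normal(0, 1, 40)
        b = shared + rng.normal(0, 1, 40)
        r = map_correlation(a, b)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        oracle = cov / (a.std() * b.std())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_common_bins_only_and_degenerate(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([2.0, 4.0, 9.0, 8.0, np.nan])
        r = map_correlation(a, b)
        assert r == pytest.approx(1.0)  # remaining bins are proportional
        assert np.isnan(map_correlation(np.ones(5), np.arange(5.0)))
        with pytest.raises(ValueError):
            map_correlation(np.array([1.0, np.nan]), np.array([np.nan, 1.0]))

    def test_split_half_positive_for_tuned_cell(self, standard_session,
                                                standard_track,
                                                standard_segments):
        segs = select_segments(standard_segments, phase="sample",
                               light_on=False)
        rm = linearized_rate_map(standard_session.spikes["u005"], segs,
                                 standard_track, bin_width=1.0)
        assert split_half_correlation(rm, smoothing_cm=10.0) > 0.5


class TestSmoothing:
    def test_truncated_window_preserves_constants(self):
        centers = np.arange(0.5, 80.0)
        vals = np.full(80, 4.2)
        sm = smooth_map(vals, centers, 10.0)
        assert np.allclose(sm, 4.2)  # edges use a shrinking window, no padding

    def test_running_average_width(self):
        centers = np.arange(0.5, 80.0)
        vals = np.zeros(80)
        vals[40] = 11.0
        sm = smooth_map(vals, centers, 10.0)
        support = np.flatnonzero(sm > 0)
        assert support.min() == 35 and support.max() == 45  # +-5 cm reach
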