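"""Poisson naive-Bayes position decoder: hand-computed and brute-force
oracles, recovery on synthetic sessions, and cross-condition schemes."""

import numpy as np
import pytest
from scipy import stats as sps

from swmaze import generate_session, segment_trajectories, track_from_session
from swmaze.core import NeuronSpec, SessionConfig, gaussian_field
from swmaze.decoder import (DecoderModel, cross_validated_decoding,
                            decode_counts, decode_window, fit_decoder,
                            train_off_test_on)
from swmaze.ratemaps import linearized_rate_map, select_segments

from conftest import tuned_roster


def model_from(rates):
    rates = np.atleast_2d(np.asarray(rates, float))
    nb = rates.shape[1]
    lo = np.arange(nb) * 10.0
    return fit_decoder({f"u{i}": rates[i] for i in range(len(rates))},
                       lo, lo + 10.0)


class TestDecodeWindow:
    def test_hand_example_zero_counts(self):
        """One neuron, f = (1, 10) Hz, n = 0, tau = 0.125: the posterior is
        proportional to (e^-0.125, e^-1.25)."""
        post, bin_ = decode_window(model_from([[1.0, 10.0]]), np.array([0]))
        expect = np.exp([-0.125, -1.25])
        expect /= expect.sum()
        assert post == pytest.approx(expect, abs=1e-12)
        assert post[0] == pytest.approx(0.7549, abs=1e-3)
        assert bin_ == 0

    def test_uniform_rates_tie_break_lowest_bin(self):
        post, bin_ = decode_window(model_from([[4.0, 4.0, 4.0]]),
                                   np.array([2]))
        assert np.allclose(post, 1.0 / 3)
        assert bin_ == 0

    def test_matches_poisson_pmf_oracle(self):
        """<= 3 neurons x <= 4 bins posterior equals the direct
        product-of-Poisson-pmf computation to 1e-10."""
        rng = np.random.default_rng(4)
        for trial in range(20):
            n_units = rng.integers(1, 4)
            n_bins = rng.integers(2, 5)
            rates = rng.uniform(0.05, 30.0, (n_units, n_bins))
            counts = rng.poisson(2.0, n_units)
            model = model_from(rates)
            post, _ = decode_counts(model, counts[None, :])
            tau = 0.125
            lik = np.prod(sps.poisson.pmf(counts[:, None], tau * model.rates),
                          axis=0)
            assert post[0] == pytest.approx(lik / lik.sum(), abs=1e-10)

    def test_roster_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_window(model_from([[1.0, 2.0]]), np.array([0, 1]))

    def test_posterior_normalized(self):
        rng = np.random.default_rng(9)
        model = model_from(rng.uniform(0, 20, (8, 8)))
        counts = rng.poisson(1.0, (50, 8))
        post, _ = decode_counts(model, counts)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestFitDecoder:
    def test_uniform_rate_stored(self):
        m = model_from([[5.0, 5.0, 5.0]])
        assert np.allclose(m.rates, 5.0)

    def test_floor_applied_to_silent_bins(self):
        m = model_from([[0.0, 3.0]])
        assert m.rates[0, 0] == 0.01  # epsilon floor, not zero

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            fit_decoder({}, np.array([0.0]), np.array([10.0]))

    def test_leave_one_out_excludes_held_trial_spikes(self, decoder_setup):
        """Training maps of the held-out trial equal a direct recount over
        the remaining trials."""
        session, track, segments = decoder_setup
        segs = select_segments(segments, phase="sample", light_on=False)
        u = session.units[3]
        rm = linearized_rate_map(session.spikes[u], segs, track)
        held = rm.trial_ids[0]
        rest = [s for s in segs if s.trial != held]
        rm_rest = linearized_rate_map(session.spikes[u], rest, track)
        mask = rm.trial_ids != held
        pooled = rm.counts[mask].sum(axis=0) / rm.occupancy[mask].sum(axis=0)
        assert np.allclose(pooled, rm_rest.avg_rate, equal_nan=True)


class TestSessionDecoding:
    def test_recovery_under_10cm(self, decoder_setup):
        """25 tuned cells, 40 trials: mean leave-one-out error < 10 cm."""
        session, track, segments = decoder_setup
        res = cross_validated_decoding(session, track, segments, "sample",
                                       False)
        assert res.status == "ok"
        assert res.mean_error_cm < 10.0
        assert res.percent_correct > 50.0

    def test_small_roster_excluded(self):
        neurons = tuned_roster(5)
        s = generate_session(SessionConfig(n_trials=8, seed=3,
                                           include_lfp=False), neurons=neurons)
        track = track_from_session(s)
        segs = segment_trajectories(s, track)
        res = cross_validated_decoding(s, track, segs, "sample", False)
        assert res.status == "excluded"

    def test_destroyed_tuning_decodes_at_chance(self, decoder_setup):
        """Per-trial bin shuffling of the training maps leaves percent
        correct near 100 / n_bins (chance-level oracle)."""
        session, track, segments = decoder_setup
        pcts = []
        for seed in range(3):
            res = cross_validated_decoding(
                session, track, segments, "sample", False,
                shuffle_rng=np.random.default_rng(seed))
            pcts.append(res.percent_correct)
        assert abs(np.mean(pcts) - 100.0 / 8) < 5.0

    def test_train_off_test_on_matches_within_condition_when_stable(
            self, decoder_setup):
        """With identical tuning in both light conditions, cross-condition
        decoding matches within-condition decoding."""
        session, track, segments = decoder_setup
        res_cross = train_off_test_on(session, track, segments, "sample")
        res_within = cross_validated_decoding(session, track, segments,
                                              "sample", True)
        assert res_cross.status == res_within.status == "ok"
        assert abs(res_cross.mean_error_cm - res_within.mean_error_cm) < 3.0

    def test_remapped_light_on_trials_raise_cross_condition_error(self):
        """Fields shifted 30 cm in light-on sample trials: training on
        light-off makes light-on decoding > 10 cm worse than within-on CV."""
        n = 25
        neurons = []
        for i in range(n):
            c = 80.0 * i / (n - 1)
            neurons.append(NeuronSpec(
                baseline_rate=0.5,
                tuning={("sample", "outbound"): gaussian_field(c, 6.0, 25.0),
                        "default": gaussian_field(c, 6.0, 25.0)}))
        cfg = SessionConfig(n_trials=40, seed=8, include_lfp=False)
        s = generate_session(cfg, neurons=neurons)
        # regenerate light-on sample spikes from shifted fields by swapping
        # the tuning only for light-on sample outbound epochs
        from swmaze.synth import replace_spikes_in_phase

        shifted = []
        for i in range(n):
            c = (80.0 * i / (n - 1) + 30.0) % 80.0
            shifted.append(NeuronSpec(baseline_rate=0.5,
                                      tuning=gaussian_field(c, 6.0, 25.0)))
        s_remap = replace_spikes_in_phase(s, shifted, "sample", True, seed=777)
        track = track_from_session(s_remap)
        segs = segment_trajectories(s_remap, track)
        res_cross = train_off_test_on(s_remap, track, segs, "sample")
        res_within = cross_validated_decoding(s_remap, track, segs, "sample",
                                              True)
        assert (res_cross.mean_error_cm - res_within.mean_error_cm) > 10.0


def test_adding_informative_neuron_does_not_hurt():
    """Mean decoding error over seeds never rises when a sharply tuned
    neuron joins the roster."""
    errs_small, errs_big = [], []
    for seed in range(5):
        base = tuned_roster(12, peak=20.0, sigma=7.0, baseline=0.5)
        extra = base + [NeuronSpec(baseline_rate=0.5,
                                   tuning=gaussian_field(35.0, 5.0, 30.0))]
        for roster, sink in ((base, errs_small), (extra, errs_big)):
            s = generate_session(SessionConfig(n_trials=20, seed=50 + seed,
                                               include_lfp=False),
                                 neurons=roster)
            track = track_from_session(s)
            segs = segment_trajectories(s, track)
            res = cross_validated_decoding(s, track, segs, "sample", False)
            sink.append(res.mean_error_cm)
    assert np.mean(errs_big) <= np.mean(errs_small) + 0.5


def test_error_decreases_with_roster_size():
    """Decoding error shrinks as the number of simultaneously recorded
    cells grows."""
    means = []
    for n in (8, 16, 32):
        errs = []
        for seed in range(3):
            s = generate_session(
                SessionConfig(n_trials=20, seed=70 + seed, include_lfp=False),
                neurons=tuned_roster(n, peak=18.0, sigma=8.0, baseline=0.5))
            track = track_from_session(s)
            segs = segment_trajectories(s, track)
            res = cross_validated_decoding(s, track, segs, "sample", False,
                                           min_cells=5)
            errs.append(res.mean_error_cm)
        means.append(np.mean(errs))
    assert means[2] < means[0]
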