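"""Reference synthetic experiments.

Each function runs one end-to-end validation study on generated data and
returns summary numbers: decoder recovery and chance controls, closed-form
spatial-information checks, false-positive rates of the spatial and goal
ANOVAs, latency recovery, phase-locking calibration, and the
direction-of-effect reproductions where tuning or goal gain is perturbed
only in light-on trials of one phase.  The acceptance script and the
regression tests both call these, so the reported numbers always come from
a fresh computation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import behavior, goal_coding, goal_decoder, light_response, ratemaps
from . import decoder as dec
from . import lfp as lfp_mod
from .core import LightEffect, NeuronSpec, SessionConfig, gaussian_field
from .stats import fisher_exact_2x2, wilcoxon_signed_rank
from .synth import (generate_brief_light_session, generate_session,
                    generate_spike_train, replace_spikes_in_phase,
                    vonmises_mrl)

__all__ = [
    "fisher_worked_examples",
    "decoder_recovery",
    "posterior_oracle_deviation",
    "spatial_information_closed_forms",
    "spatial_anova_error_rates",
    "goal_anova_false_positive_rate",
    "latency_recovery_rate",
    "phase_locking_calibration",
    "sample_remap_effects",
    "goal_gain_reduction_effects",
]

# Published group counts from the study's Results (inputs to the worked
# examples): (hits_1, n_1, hits_2, n_2) per comparison.
FISHER_EXAMPLES = {
    "t1": (16, 183, 78, 445),    # excited cells, dHPC vs vHPC silencing
    "t2": (41, 183, 128, 445),   # all modulated cells, dHPC vs vHPC
    "t3": (187, 427, 195, 427),  # spatially modulated, sample off vs on, dHPC
    "t4": (170, 393, 180, 393),  # sample off vs on, vHPC
    "t5": (215, 438, 206, 438),  # choice off vs on, dHPC
    "t6": (155, 340, 163, 340),  # choice off vs on, vHPC
}


def fisher_worked_examples() -> dict:
    """Two-sided Fisher exact p for each published 2x2 comparison."""
    out = {}
    for key, (h1, n1, h2, n2) in FISHER_EXAMPLES.items():
        out[key] = {"value": fisher_exact_2x2(h1, n1 - h1, h2, n2 - h2),
                    "n": n1 + n2}
    return out


def _tuned_roster(n, peak, sigma, baseline, **kw):
    return [NeuronSpec(baseline_rate=baseline,
                       tuning=gaussian_field(80.0 * i / max(n - 1, 1), sigma,
                                             peak), **kw)
            for i in range(n)]


def decoder_recovery(seed: int, n_cells: int = 25, n_trials: int = 40) -> dict:
    """Leave-one-out decoding of a tuned population plus its chance control."""
    s = generate_session(SessionConfig(n_trials=n_trials, seed=seed,
                                       include_lfp=False),
                         neurons=_tuned_roster(n_cells, 25.0, 6.0, 0.5))
    track = behavior.track_from_session(s)
    segments = behavior.segment_trajectories(s, track)
    res = dec.cross_validated_decoding(s, track, segments, "sample", False)
    chance = np.mean([
        dec.cross_validated_decoding(
            s, track, segments, "sample", False,
            shuffle_rng=np.random.default_rng(seed + 1 + k)).percent_correct
        for k in range(5)])
    return {
        "mean_error_cm": res.mean_error_cm,
        "percent_correct": res.percent_correct,
        "chance_percent_correct": float(chance),
        "chance_nominal": 100.0 / 8,
        "n_windows": res.n_windows,
    }


def posterior_oracle_deviation(seed: int, n_instances: int = 30) -> float:
    """Max |posterior - brute-force Poisson-pmf oracle| on small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_units = int(rng.integers(1, 4))
        n_bins = int(rng.integers(2, 5))
        rates = rng.uniform(0.05, 30.0, (n_units, n_bins))
        counts = rng.poisson(2.0, n_units)
        lo = np.arange(n_bins) * 10.0
        model = dec.fit_decoder({f"u{i}": rates[i] for i in range(n_units)},
                                lo, lo + 10.0)
        post, _ = dec.decode_counts(model, counts[None, :])
        lik = np.prod(sps.poisson.pmf(counts[:, None], 0.125 * model.rates),
                      axis=0)
        worst = max(worst, float(np.max(np.abs(post[0] - lik / lik.sum()))))
    return worst


def spatial_information_closed_forms() -> dict:
    """Single-bin firing among 8 equal bins (3 bits) and a uniform map (0)."""
    single = np.zeros(8)
    single[2] = 24.0
    return {
        "single_bin_bits": ratemaps.spatial_information(single, np.ones(8)),
        "uniform_bits": ratemaps.spatial_information(np.full(8, 6.0),
                                                     np.ones(8)),
    }


def _poisson_ratemap(rng, rates_per_bin, n_trials, dwell_s):
    counts = rng.poisson(np.asarray(rates_per_bin) * dwell_s,
                         (n_trials, len(rates_per_bin)))
    occ = np.full_like(counts, dwell_s, dtype=float)
    lo = np.arange(len(rates_per_bin)) * 10.0
    return ratemaps.RateMap(lo, lo + 10.0, np.arange(n_trials),
                            counts.astype(float), occ)


def spatial_anova_error_rates(seed: int, n_cells: int = 2000,
                              n_trials: int = 20, dwell_s: float = 0.4) -> dict:
    """Type-I rate of the position RM-ANOVA on untuned Poisson cells and its
    power against a planted 10 -> 2 Hz field."""
    rng = np.random.default_rng(seed)
    fp = 0
    for _ in range(n_cells):
        rm = _poisson_ratemap(rng, np.full(8, 5.0), n_trials, dwell_s)
        fp += ratemaps.spatial_modulation_test(rm).significant
    field = 2.0 + 8.0 * np.exp(-0.5 * ((np.arange(8) - 3.5) / 1.2) ** 2)
    hits = 0
    n_power = 200
    for _ in range(n_power):
        rm = _poisson_ratemap(rng, field, n_trials, dwell_s)
        hits += ratemaps.spatial_modulation_test(rm).significant
    return {"false_positive_pct": 100.0 * fp / n_cells,
            "power_pct": 100.0 * hits / n_power,
            "n_cells": n_cells}


def goal_anova_false_positive_rate(seed: int, n_cells: int = 2000,
                                   n_trials: int = 20,
                                   dwell_s: float = 2.0) -> dict:
    """Type-I rate of the goal-selectivity ANOVA (alpha = 0.025) on cells
    with identical rates in both goal arms."""
    rng = np.random.default_rng(seed)
    fp = 0
    for _ in range(n_cells):
        L = rng.poisson(8.0 * dwell_s, (n_trials, 3)) / dwell_s
        R = rng.poisson(8.0 * dwell_s, (n_trials, 3)) / dwell_s
        sel = goal_coding.goal_selectivity_test({"off": {"L": L, "R": R}})
        p = sel.p_by_condition["off"]
        fp += bool(np.isfinite(p) and p < 0.025)
    return {"false_positive_pct": 100.0 * fp / n_cells, "n_cells": n_cells}


def latency_recovery_rate(seed: int, n_runs: int = 50,
                          planted_ms: float = 40.0) -> dict:
    """Fraction of runs recovering a planted silencing latency within one
    10 ms bin."""
    hits = 0
    for k in range(n_runs):
        spec = NeuronSpec(baseline_rate=20.0,
                          light=LightEffect(-1, 1.0, latency_ms=planted_ms,
                                            tau_ms=0.0))
        bl = generate_brief_light_session([spec], n_pulses=60,
                                          seed=seed * 1000 + k)
        lat = light_response.response_latency(bl.spikes["u000"],
                                              bl.light_onsets,
                                              rng=seed * 1000 + k)
        hits += lat is not None and abs(lat - planted_ms) <= 10.0
    return {"recovered_pct": 100.0 * hits / n_runs, "n_runs": n_runs}


def phase_locking_calibration(seed: int) -> dict:
    """MRL of kappa = 2 spiking vs the closed form, and the Rayleigh series
    p against a Monte-Carlo null at n = 50."""
    spec = NeuronSpec(baseline_rate=5.0, theta_kappa=2.0, theta_mu=1.0)
    t = np.arange(0, 2100, 0.04)
    st = generate_spike_train(spec, t, np.zeros_like(t), theta_freq=8.0,
                              rng=np.random.default_rng(seed))[:10000]
    phases = (2 * np.pi * 8.0 * st) % (2 * np.pi)
    mrl_dev = abs(lfp_mod.mean_resultant_length(phases) - vonmises_mrl(2.0))

    rng = np.random.default_rng(seed + 1)
    n = 50
    null_R = np.array([lfp_mod.mean_resultant_length(
        rng.uniform(0, 2 * np.pi, n)) for _ in range(20000)])
    worst = 0.0
    for _ in range(200):
        ph = rng.vonmises(0.0, rng.uniform(0, 0.6), n)
        _, p = lfp_mod.rayleigh_test(ph)
        p_mc = float(np.mean(null_R >= lfp_mod.mean_resultant_length(ph)))
        worst = max(worst, abs(p - p_mc))
    return {"mrl_abs_dev": float(mrl_dev), "n_spikes": len(st),
            "rayleigh_max_abs_dev": worst}


def sample_remap_effects(seed: int, n_cells: int = 100) -> dict:
    """Remap fields only in light-on sample runs and measure the fallout.

    Reproduces two observed silencing signatures in direction: the
    light-on/off map correlation drops in the perturbed (sample) phase but
    not the control (choice) phase, and decoding light-on trials from
    light-off training raises the error relative to within-condition
    decoding.
    """
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, 80.0, n_cells)
    neurons = [NeuronSpec(baseline_rate=0.5,
                          tuning=gaussian_field(c, 7.0, 18.0))
               for c in centers]
    s = generate_session(SessionConfig(n_trials=40, seed=seed,
                                       include_lfp=False), neurons=neurons)
    shifted = [NeuronSpec(baseline_rate=0.5,
                          tuning=gaussian_field((c + 30.0) % 80.0, 7.0, 18.0))
               for c in centers]
    s_remap = replace_spikes_in_phase(s, shifted, "sample", True, seed=seed)
    track = behavior.track_from_session(s_remap)
    segments = behavior.segment_trajectories(s_remap, track)

    r_sample, r_choice = [], []
    for u in s_remap.units:
        maps = {}
        for phase in ("sample", "choice"):
            for cond, flag in (("off", False), ("on", True)):
                segs = ratemaps.select_segments(segments, phase=phase,
                                                light_on=flag)
                rmap = ratemaps.linearized_rate_map(
                    s_remap.spikes[u], segs, track, bin_width=1.0,
                    smoothing_cm=10.0)
                maps[(phase, cond)] = rmap.avg_smoothed
        try:
            r_sample.append(ratemaps.map_correlation(maps[("sample", "off")],
                                                     maps[("sample", "on")]))
            r_choice.append(ratemaps.map_correlation(maps[("choice", "off")],
                                                     maps[("choice", "on")]))
        except ValueError:
            continue
    r_sample, r_choice = np.asarray(r_sample), np.asarray(r_choice)
    ok = np.isfinite(r_sample) & np.isfinite(r_choice)
    p_paired = wilcoxon_signed_rank(r_sample[ok] - r_choice[ok])

    res_cross = dec.train_off_test_on(s_remap, track, segments, "sample")
    res_within = dec.cross_validated_decoding(s_remap, track, segments,
                                              "sample", True)
    return {
        "r_sample_mean": float(np.nanmean(r_sample)),
        "r_choice_mean": float(np.nanmean(r_choice)),
        "paired_wilcoxon_p": p_paired,
        "n_cells": int(ok.sum()),
        "cross_error_cm": res_cross.mean_error_cm,
        "within_on_error_cm": res_within.mean_error_cm,
        "error_increase_cm": res_cross.mean_error_cm - res_within.mean_error_cm,
    }


def goal_gain_reduction_effects(seed: int, n_cells: int = 90,
                                n_decode_units: int = 18,
                                n_repeats: int = 20) -> dict:
    """Reduce goal gain only in light-on sample trials and measure the
    goal-index drop (position x light ANOVA) and the goal-decoding drop.

    Reproduces the direction of the observed effect of sample-phase
    silencing on prefrontal goal coding.
    """
    # goal-index population: many selective cells
    neurons = [NeuronSpec(baseline_rate=3.0, goal_gain=3.0,
                          preferred_goal="L" if i % 2 else "R")
               for i in range(n_cells)]
    s = generate_session(SessionConfig(n_trials=40, seed=seed,
                                       include_lfp=False), neurons=neurons)
    reduced = [NeuronSpec(baseline_rate=3.0, goal_gain=1.2,
                          preferred_goal=sp.preferred_goal) for sp in neurons]
    s_red = replace_spikes_in_phase(s, reduced, "sample", True, seed=seed)
    track = behavior.track_from_session(s_red)
    segments = behavior.segment_trajectories(s_red, track)

    values, light_fac, pos_fac = [], [], []
    off_idx, on_idx = [], []
    for j, u in enumerate(s_red.units):
        pref = neurons[j].preferred_goal
        for cond, flag in (("off", False), ("on", True)):
            prof = goal_coding.goal_arm_rates(s_red.spikes[u], segments,
                                              track, "sample", flag)
            gip = goal_coding.goal_index_profile(prof, pref)
            idx = gip.index
            # goal-arm positions only (outbound arm bins, goal, inbound arm bins)
            arm = [i for i, lab in enumerate(gip.position_labels)
                   if lab in ("out_40-60", "out_50-70", "out_60-80", "goal",
                              "in_80-60", "in_70-50", "in_60-40")]
            for i in arm:
                if np.isfinite(idx[i]):
                    values.append(idx[i])
                    light_fac.append(cond)
                    pos_fac.append(i)
            mean_idx = float(np.nanmean(idx[arm]))
            (off_idx if cond == "off" else on_idx).append(mean_idx)
    anova = goal_coding.two_way_anova(np.array(values), np.array(light_fac),
                                      np.array(pos_fac))

    # goal-decoding population: a separate session-sized roster
    dec_neurons = neurons[:n_decode_units]
    s2 = generate_session(SessionConfig(n_trials=40, seed=seed + 1,
                                        include_lfp=False),
                          neurons=dec_neurons)
    s2_red = replace_spikes_in_phase(
        s2, [NeuronSpec(baseline_rate=3.0, goal_gain=1.0,
                        preferred_goal=sp.preferred_goal)
             for sp in dec_neurons], "sample", True, seed=seed + 1)
    track2 = behavior.track_from_session(s2_red)
    segs2 = behavior.segment_trajectories(s2_red, track2)
    accs = {}
    for cond, flag in (("off", False), ("on", True)):
        gv = goal_decoder.build_goal_vectors(s2_red, track2, segs2, "sample",
                                             flag)
        res = goal_decoder.decode_goal_by_position(
            gv, n_pairs=10, n_repeats=n_repeats,
            rng=np.random.default_rng(seed + 2))
        labels = np.array(res.position_labels)
        arm = np.array([lab in ("out_40-60", "out_50-70", "out_60-80", "goal")
                        for lab in labels])
        accs[cond] = float(np.mean(res.percent_correct[arm]))
    return {
        "index_off_mean": float(np.mean(off_idx)),
        "index_on_mean": float(np.mean(on_idx)),
        "light_anova_p": anova["p_a"],
        "n_cells": n_cells,
        "goal_acc_off_pct": accs["off"],
        "goal_acc_on_pct": accs["on"],
        "goal_acc_drop_pct": accs["off"] - accs["on"],
    }
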