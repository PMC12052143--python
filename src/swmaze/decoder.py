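"""Poisson naive-Bayes decoding of linearized position from population
spike counts.

The posterior over position bins is, up to normalization,
``P(pos | n) ~ prod_i (tau f_i(pos))^{n_i} e^{-tau f_i(pos)}`` with a
uniform prior; evaluation is in the log domain and the decoded bin is the
posterior argmax (lowest index on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .behavior import SPEED_THRESHOLD, LinearizedTrack, TrajectorySegment
from .core import Session
from .ratemaps import linearized_rate_map, select_segments

__all__ = ["DecoderModel", "DecodingResult", "fit_decoder", "decode_window",
           "decode_counts", "cross_validated_decoding", "train_off_test_on"]

RATE_FLOOR = 0.01  # Hz; regularizes zero training rates
TAU = 0.125  # s, decoding window length
STEP = 0.025  # s, window step (100 ms overlap)
MIN_CELLS = 10


@dataclass
class DecoderModel:
    units: list[str]
    bin_lo: np.ndarray
    bin_hi: np.ndarray
    rates: np.ndarray  # (n_units, n_bins), floored at RATE_FLOOR

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_lo + self.bin_hi) / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_lo)


@dataclass
class DecodingResult:
    status: str  # "ok" | "excluded"
    mean_error_cm: float = np.nan
    percent_correct: float = np.nan
    n_windows: int = 0
    n_units: int = 0
    table: pd.DataFrame | None = None
    detail: dict = field(default_factory=dict)


def fit_decoder(rate_maps: dict[str, np.ndarray], bin_lo: np.ndarray,
                bin_hi: np.ndarray, floor: float = RATE_FLOOR) -> DecoderModel:
    """Build a decoder from per-unit averaged rate maps (Hz per bin)."""
    if not rate_maps:
        raise ValueError("empty neuron roster")
    units = sorted(rate_maps)
    rates = np.vstack([np.asarray(rate_maps[u], float) for u in units])
    rates = np.where(np.isfinite(rates), rates, 0.0)
    rates = np.clip(rates, floor, None)
    return DecoderModel(units, np.asarray(bin_lo), np.asarray(bin_hi), rates)


def decode_counts(model: DecoderModel, counts: np.ndarray,
                  tau: float = TAU) -> tuple[np.ndarray, np.ndarray]:
    """Posterior over bins and decoded bin for each count vector.

    ``counts`` is (n_windows, n_units); returns (posteriors (W, B),
    decoded bin indices (W,)).  The n_i! term is constant over position and
    drops out of the normalized posterior.
    """
    counts = np.atleast_2d(np.asarray(counts, float))
    if counts.shape[1] != len(model.units):
        raise ValueError("count vector roster does not match model roster")
    logf = np.log(tau * model.rates)  # (U, B)
    loglik = counts @ logf - tau * model.rates.sum(axis=0)[None, :]
    post = np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))
    return post, np.argmax(post, axis=1)


def decode_window(model: DecoderModel, counts: np.ndarray, tau: float = TAU):
    """Single-window convenience wrapper around :func:`decode_counts`."""
    post, dec = decode_counts(model, np.asarray(counts)[None, :], tau)
    return post[0], int(dec[0])


def _window_starts(t0: float, t1: float, tau: float, step: float) -> np.ndarray:
    if t1 - t0 < tau:
        return np.array([])
    return t0 + np.arange(0, t1 - t0 - tau + 1e-9, step)


def _count_matrix(spikes_by_unit: list[np.ndarray], starts: np.ndarray,
                  tau: float) -> np.ndarray:
    counts = np.empty((len(starts), len(spikes_by_unit)))
    for j, st in enumerate(spikes_by_unit):
        counts[:, j] = np.searchsorted(st, starts + tau) - np.searchsorted(st, starts)
    return counts


def _true_bins(model: DecoderModel, d: np.ndarray) -> np.ndarray:
    """Bin containing each position; half-open bins, last bin closed."""
    edges = np.append(model.bin_lo, model.bin_hi[-1])
    idx = np.digitize(d, edges) - 1
    return np.clip(idx, 0, model.n_bins - 1)


def _trial_bin_stats(session: Session, track: LinearizedTrack,
                     segments: list[TrajectorySegment], units: list[str],
                     bin_width: float):
    """Per-trial spike counts and occupancy per bin, for pooled training maps."""
    trial_ids = sorted({s.trial for s in segments})
    per_trial = {}
    for tr in trial_ids:
        segs = [s for s in segments if s.trial == tr]
        rm = linearized_rate_map(np.array([]), segs, track, bin_width=bin_width)
        occ = rm.occupancy.sum(axis=0)
        cnt = np.zeros((len(units), rm.n_bins))
        for j, u in enumerate(units):
            rm_u = linearized_rate_map(session.spikes[u], segs, track,
                                       bin_width=bin_width)
            cnt[j] = rm_u.counts.sum(axis=0)
        per_trial[tr] = (cnt, occ, rm.bin_lo, rm.bin_hi)
    return per_trial


def _decode_trials(session: Session, track: LinearizedTrack,
                   train_stats: dict, test_segments: list[TrajectorySegment],
                   units: list[str], leave_one_out: bool, tau: float,
                   step: float, speed_min: float,
                   shuffle_rng: np.random.Generator | None = None,
                   ) -> DecodingResult:
    some = next(iter(train_stats.values()))
    bin_lo, bin_hi = some[2], some[3]
    total_cnt = np.sum([c for c, *_ in train_stats.values()], axis=0)
    total_occ = np.sum([o for _, o, *_ in train_stats.values()], axis=0)

    rows = []
    speed = track.speed
    for seg in test_segments:
        cnt, occ = total_cnt, total_occ
        if leave_one_out and seg.trial in train_stats:
            c_t, o_t, *_ = train_stats[seg.trial]
            cnt, occ = cnt - c_t, occ - o_t
        with np.errstate(divide="ignore", invalid="ignore"):
            maps = np.where(occ > 0, cnt / occ, 0.0)
        model = fit_decoder({u: maps[j] for j, u in enumerate(units)},
                            bin_lo, bin_hi)
        starts = _window_starts(seg.t_start, seg.t_end, tau, step)
        if len(starts) == 0:
            continue
        centers = starts + tau / 2.0
        v = np.interp(centers, track.t, speed)
        keep = v >= speed_min
        starts, centers = starts[keep], centers[keep]
        if len(starts) == 0:
            continue
        counts = _count_matrix([session.spikes[u] for u in units], starts, tau)
        if shuffle_rng is not None:
            counts = counts[shuffle_rng.permutation(len(counts))]
        post, dec = decode_counts(model, counts, tau)
        true_d = track.d_at(centers)
        true_bin = _true_bins(model, true_d)
        err = np.abs(model.centers[dec] - true_d)
        for k in range(len(starts)):
            rows.append((seg.trial, centers[k], int(true_bin[k]), int(dec[k]),
                         float(post[k].max()), float(err[k])))

    if not rows:
        return DecodingResult("excluded", n_units=len(units),
                              detail={"reason": "no decodable windows"})
    table = pd.DataFrame(rows, columns=["trial", "t_center", "true_bin",
                                        "decoded_bin", "max_posterior",
                                        "error_cm"])
    correct = (table.true_bin == table.decoded_bin).mean()
    return DecodingResult("ok", float(table.error_cm.mean()),
                          100.0 * float(correct), len(table), len(units), table)


def cross_validated_decoding(session: Session, track: LinearizedTrack,
                             segments: list[TrajectorySegment], phase: str,
                             light_on: bool, bin_width: float = 10.0,
                             min_cells: int = MIN_CELLS, tau: float = TAU,
                             step: float = STEP,
                             speed_min: float = SPEED_THRESHOLD,
                             shuffle_rng: np.random.Generator | None = None,
                             ) -> DecodingResult:
    """Leave-one-trial-out decoding within one phase and light condition.

    Training maps for each held-out trial pool the spikes and occupancy of
    all other trials of the same condition; reported are the mean absolute
    decoding error (cm) and the percentage of windows whose decoded 10 cm bin
    equals the bin containing the true position at the window center.
    Sessions with <= ``min_cells`` simultaneously recorded units are excluded.

    ``shuffle_rng`` enables the tuning-destroyed control: the count vectors
    of each held-out trial are permuted across its windows, severing the
    spike-count/position relation while keeping both marginals; decoding
    should then sit at chance (about 100 / n_bins % for a uniform traversal).
    """
    units = session.units
    if len(units) <= min_cells:
        return DecodingResult("excluded", n_units=len(units),
                              detail={"reason": f"<= {min_cells} cells"})
    segs = select_segments(segments, phase=phase, light_on=light_on)
    if not segs:
        return DecodingResult("excluded", n_units=len(units),
                              detail={"reason": "no segments"})
    stats = _trial_bin_stats(session, track, segs, units, bin_width)
    return _decode_trials(session, track, stats, segs, units, True, tau, step,
                          speed_min, shuffle_rng)


def train_off_test_on(session: Session, track: LinearizedTrack,
                      segments: list[TrajectorySegment], phase: str,
                      bin_width: float = 10.0, min_cells: int = MIN_CELLS,
                      tau: float = TAU, step: float = STEP,
                      speed_min: float = SPEED_THRESHOLD) -> DecodingResult:
    """Fit on all light-off trials of a phase, decode every light-on trial."""
    units = session.units
    if len(units) <= min_cells:
        return DecodingResult("excluded", n_units=len(units),
                              detail={"reason": f"<= {min_cells} cells"})
    train = select_segments(segments, phase=phase, light_on=False)
    test = select_segments(segments, phase=phase, light_on=True)
    if not train or not test:
        return DecodingResult("excluded", n_units=len(units),
                              detail={"reason": "missing condition"})
    stats = _trial_bin_stats(session, track, train, units, bin_width)
    return _decode_trials(session, track, stats, test, units, False, tau, step,
                          speed_min)
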