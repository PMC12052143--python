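"""Linearized firing-rate maps, spatial-modulation testing, Skaggs spatial
information and map-similarity correlations.

A rate map is spikes/occupancy per linear position bin, restricted to
running epochs (speed >= 5 cm/s); bins with zero occupancy are missing
(NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import SPEED_THRESHOLD, LinearizedTrack, TrajectorySegment

__all__ = [
    "RateMap",
    "SpatialTestResult",
    "select_segments",
    "linearized_rate_map",
    "spatial_modulation_test",
    "spatial_information",
    "map_correlation",
    "split_half_correlation",
    "smooth_map",
]


def select_segments(segments: list[TrajectorySegment], phase: str | None = None,
                    light_on: bool | None = None, kinds=("outbound",),
                    goal: str | None = None, complete_only: bool = True):
    out = []
    for s in segments:
        if phase is not None and s.phase != phase:
            continue
        if light_on is not None and s.light_on != light_on:
            continue
        if kinds is not None and s.kind not in kinds:
            continue
        if goal is not None and s.goal != goal:
            continue
        if complete_only and not s.complete:
            continue
        out.append(s)
    return out


def _bin_edges(lo: float, hi: float, width: float, overlap: float):
    if not width > overlap >= 0:
        raise ValueError("need bin_width > bin_overlap >= 0")
    step = width - overlap
    starts = np.arange(lo, hi - width + step / 2, step)
    return starts, starts + width


@dataclass
class RateMap:
    bin_lo: np.ndarray
    bin_hi: np.ndarray
    trial_ids: np.ndarray
    counts: np.ndarray  # (n_trials, n_bins) spike counts
    occupancy: np.ndarray  # (n_trials, n_bins) seconds
    metadata: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_lo + self.bin_hi) / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_lo)

    @property
    def rate(self) -> np.ndarray:
        """Per-trial rates; NaN where a trial never occupied a bin."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.occupancy > 0, self.counts / self.occupancy, np.nan)

    def averaged(self, trial_mask: np.ndarray | None = None) -> np.ndarray:
        """Trial-averaged map: pooled spikes / pooled occupancy per bin."""
        c, o = self.counts, self.occupancy
        if trial_mask is not None:
            c, o = c[trial_mask], o[trial_mask]
        csum, osum = c.sum(axis=0), o.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(osum > 0, csum / osum, np.nan)

    @property
    def avg_rate(self) -> np.ndarray:
        return self.averaged()

    @property
    def avg_smoothed(self) -> np.ndarray:
        w = self.metadata.get("smoothing_cm")
        avg = self.averaged()
        return smooth_map(avg, self.centers, w) if w else avg

    def to_table(self, unit: str = "", condition: str = "") -> pd.DataFrame:
        avg = self.avg_rate
        occ = self.occupancy.sum(axis=0)
        return pd.DataFrame({
            "unit": unit, "condition": condition,
            "bin_center_cm": self.centers,
            "rate_hz": avg, "occupancy_s": occ,
        })


def smooth_map(values: np.ndarray, centers: np.ndarray,
               window_cm: float) -> np.ndarray:
    """Centered running average over ``window_cm``, truncated at track ends.

    Missing bins (NaN) are ignored inside the window rather than padded.
    """
    half = window_cm / 2.0 + 1e-9
    out = np.empty_like(values, dtype=float)
    for i, c in enumerate(centers):
        sel = np.abs(centers - c) <= half
        vals = values[sel]
        out[i] = np.nan if np.all(np.isnan(vals)) else np.nanmean(vals)
    return out


def linearized_rate_map(spike_times: np.ndarray, segments: list[TrajectorySegment],
                        track: LinearizedTrack, bin_width: float = 10.0,
                        bin_overlap: float = 0.0,
                        speed_min: float = SPEED_THRESHOLD,
                        smoothing_cm: float | None = None,
                        d_range: tuple[float, float] = (0.0, 80.0)) -> RateMap:
    """Per-trial linearized firing-rate map over the given segments.

    Only samples (and spikes) with running speed >= ``speed_min`` and a valid
    on-track position contribute.  With overlapping bins every sample/spike
    is credited to each bin containing it; the final bin is closed on the
    right, all others are half-open ``[lo, hi)``.
    """
    if not segments:
        raise ValueError("no segments supplied")
    spike_times = np.asarray(spike_times, float)
    lo_arr, hi_arr = _bin_edges(d_range[0], d_range[1], bin_width, bin_overlap)
    n_bins = len(lo_arr)
    speed = track.speed
    dt = track.dt

    trial_ids = np.array(sorted({s.trial for s in segments}))
    tmap = {tr: k for k, tr in enumerate(trial_ids)}
    counts = np.zeros((len(trial_ids), n_bins))
    occupancy = np.zeros((len(trial_ids), n_bins))

    sp_speed = np.interp(spike_times, track.t, speed) if len(spike_times) else spike_times
    sp_d = np.interp(spike_times, track.t, track.d) if len(spike_times) else spike_times

    for seg in segments:
        row = tmap[seg.trial]
        m = (track.t >= seg.t_start) & (track.t < seg.t_end) & track.valid
        m &= speed >= speed_min
        d_samp = track.d[m]
        sm = (spike_times >= seg.t_start) & (spike_times < seg.t_end)
        sm &= sp_speed >= speed_min
        d_spk = sp_d[sm]
        for b in range(n_bins):
            lo, hi = lo_arr[b], hi_arr[b]
            if b == n_bins - 1 or hi >= d_range[1]:
                in_bin = (d_samp >= lo) & (d_samp <= hi)
                in_bin_s = (d_spk >= lo) & (d_spk <= hi)
            else:
                in_bin = (d_samp >= lo) & (d_samp < hi)
                in_bin_s = (d_spk >= lo) & (d_spk < hi)
            occupancy[row, b] += in_bin.sum() * dt
            counts[row, b] += in_bin_s.sum()

    if occupancy.sum() == 0:
        raise ValueError("empty rate map: no qualifying samples in any bin")
    meta = {"bin_width": bin_width, "bin_overlap": bin_overlap,
            "speed_min": speed_min, "smoothing_cm": smoothing_cm,
            "kinds": sorted({s.kind for s in segments}),
            "phases": sorted({s.phase for s in segments})}
    return RateMap(lo_arr, hi_arr, trial_ids, counts, occupancy, meta)


@dataclass
class SpatialTestResult:
    F: float
    p: float
    significant: bool
    n_trials: int
    n_bins: int
    note: str = ""


def spatial_modulation_test(rate_map: RateMap, alpha: float = 0.05) -> SpatialTestResult:
    """One-way repeated-measures ANOVA with factor position, trials as subjects.

    Trials missing any bin after speed filtering are dropped (complete-case),
    keeping the balanced design the RM-ANOVA requires.  ``F = MS_position /
    MS_(position x trial)``.
    """
    rates = rate_map.rate
    complete = ~np.isnan(rates).any(axis=1)
    x = rates[complete]
    n, b = x.shape
    if n < 2 or b < 2:
        return SpatialTestResult(np.nan, np.nan, False, n, b,
                                 note="fewer than 2 complete trials")
    grand = x.mean()
    mean_bin = x.mean(axis=0)
    mean_tr = x.mean(axis=1)
    ss_pos = n * np.sum((mean_bin - grand) ** 2)
    resid = x - mean_bin[None, :] - mean_tr[:, None] + grand
    ss_err = np.sum(resid ** 2)
    df_pos, df_err = b - 1, (b - 1) * (n - 1)
    if ss_err <= 1e-300:
        if ss_pos <= 1e-300:
            return SpatialTestResult(0.0, 1.0, False, n, b, note="no variance")
        return SpatialTestResult(np.inf, 0.0, True, n, b,
                                 note="zero within-position variance")
    F = (ss_pos / df_pos) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_pos, df_err))
    return SpatialTestResult(float(F), p, p < alpha, n, b)


def spatial_information(rate_map_or_rates, occupancy: np.ndarray | None = None) -> float:
    """Skaggs spatial information (bits/spike).

    ``SI = sum_i p_i (f_i/f) log2(f_i/f)`` with occupancy probabilities
    ``p_i``, bin rates ``f_i`` and occupancy-weighted mean rate ``f``.
    Zero-rate bins contribute 0 (x log x -> 0); a silent cell (f = 0) is
    undefined and raises.
    """
    if occupancy is None:
        rm: RateMap = rate_map_or_rates
        rates = rm.avg_rate
        occupancy = rm.occupancy.sum(axis=0)
    else:
        rates = np.asarray(rate_map_or_rates, float)
        occupancy = np.asarray(occupancy, float)
    ok = (occupancy > 0) & np.isfinite(rates)
    rates, occupancy = rates[ok], occupancy[ok]
    if occupancy.sum() <= 0:
        raise ValueError("no occupancy")
    p = occupancy / occupancy.sum()
    f = float(np.sum(p * rates))
    if f <= 0:
        raise ValueError("silent cell: spatial information undefined")
    ratio = rates / f
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def map_correlation(map_a: np.ndarray, map_b: np.ndarray,
                    min_bins: int = 3) -> float:
    """Pearson r between two averaged maps over their common non-missing bins.

    Returns NaN when either map has zero variance over the common bins.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_bins:
        raise ValueError(f"fewer than {min_bins} common bins")
    a, b = a[ok], b[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def split_half_correlation(rate_map: RateMap,
                           smoothing_cm: float | None = None) -> float:
    """Correlate the even-trial average with the odd-trial average."""
    idx = np.arange(len(rate_map.trial_ids))
    even = rate_map.averaged(idx % 2 == 0)
    odd = rate_map.averaged(idx % 2 == 1)
    if smoothing_cm:
        even = smooth_map(even, rate_map.centers, smoothing_cm)
        odd = smooth_map(odd, rate_map.centers, smoothing_cm)
    return map_correlation(even, odd)
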