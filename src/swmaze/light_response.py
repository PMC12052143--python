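"""Detection of light-evoked firing-rate changes and surrogate-based
response-latency estimation.

Units are labeled excited/inhibited when the rate in the 0.5 s after light
onset differs from the 0.5 s immediately before (paired Wilcoxon signed-rank
across pulses, p < 0.05).  Latency comes from comparing the baseline-
subtracted PSTH against a surrogate distribution built solely from
pre-onset activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PSTH", "LightResponse", "compute_psth", "classify_light_response",
           "response_latency"]

BIN_MS = 10.0
PSTH_WINDOW_S = 0.5
MAX_LATENCY_MS = 200.0


@dataclass
class PSTH:
    """Trial-aligned rate histogram around light onset (+-500 ms, 10 ms bins)."""

    bin_left_ms: np.ndarray  # left edges, ms relative to onset
    counts: np.ndarray  # (n_trials, n_bins)
    bin_s: float

    @property
    def rate(self) -> np.ndarray:
        return self.counts.mean(axis=0) / self.bin_s

    @property
    def baseline(self) -> float:
        """Mean rate over the 0.5 s window before onset."""
        pre = self.bin_left_ms < 0
        return float(self.counts[:, pre].mean() / self.bin_s)

    @property
    def normalized_rate(self) -> np.ndarray:
        return self.rate - self.baseline

    def to_table(self, unit: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "unit": unit, "bin_ms": self.bin_left_ms + BIN_MS / 2,
            "rate_hz": self.rate, "normalized_rate_hz": self.normalized_rate,
        })


@dataclass
class LightResponse:
    label: str  # excited | inhibited | none
    p: float
    percent_change: float  # 100 * (post - pre) / pre; NaN if silent baseline
    latency_ms: float | None = None


def _bin_counts(spikes: np.ndarray, onsets: np.ndarray, left_edges_s: np.ndarray,
                bin_s: float) -> np.ndarray:
    """Spike counts per (pulse, bin) for bins at onset + left_edges_s."""
    out = np.empty((len(onsets), len(left_edges_s)))
    edges = np.append(left_edges_s, left_edges_s[-1] + bin_s)
    for i, onset in enumerate(onsets):
        out[i] = np.histogram(spikes - onset, bins=edges)[0]
    return out


def compute_psth(spikes: np.ndarray, onsets: np.ndarray,
                 window_s: float = PSTH_WINDOW_S, bin_ms: float = BIN_MS) -> PSTH:
    bin_s = bin_ms / 1000.0
    left = np.arange(-window_s, window_s, bin_s)
    counts = _bin_counts(np.asarray(spikes, float), np.asarray(onsets, float),
                         left, bin_s)
    return PSTH(left * 1000.0, counts, bin_s)


def classify_light_response(spikes: np.ndarray, onsets: np.ndarray,
                            window_s: float = PSTH_WINDOW_S,
                            alpha: float = 0.05) -> LightResponse:
    """Excited/inhibited/none from paired pre vs post pulse rates.

    Per pulse the rate in ``[onset, onset + window_s)`` is compared with
    ``[onset - window_s, onset)`` by Wilcoxon signed-rank; the direction is
    the sign of the mean difference.
    """
    spikes = np.asarray(spikes, float)
    onsets = np.asarray(onsets, float)
    if len(onsets) < 10:
        raise ValueError("need at least 10 light pulses")
    pre = np.array([np.sum((spikes >= o - window_s) & (spikes < o)) for o in onsets])
    post = np.array([np.sum((spikes >= o) & (spikes < o + window_s)) for o in onsets])
    pre_rate, post_rate = pre / window_s, post / window_s
    diffs = post_rate - pre_rate
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(sps.wilcoxon(post_rate, pre_rate, zero_method="wilcox").pvalue)
    label = "none"
    if p < alpha:
        label = "excited" if diffs.mean() > 0 else "inhibited"
    base = pre_rate.mean()
    pct = 100.0 * (post_rate.mean() - base) / base if base > 0 else np.nan
    return LightResponse(label, p, pct)


def response_latency(spikes: np.ndarray, onsets: np.ndarray,
                     n_surrogates: int = 1000,
                     rng: np.random.Generator | int | None = None,
                     pre_s: float = 1.0, bin_ms: float = BIN_MS,
                     max_latency_ms: float = MAX_LATENCY_MS,
                     percentile: float = 95.0) -> float | None:
    """Latency (ms) of the light response, or None if no reliable response.

    Surrogates: each pulse's 1 s pre-onset rate vector (10 ms bins) is
    circularly shifted by an independent uniform offset; the trial-averaged
    surrogate PSTH's second half minus first half, over ``n_surrogates``
    repeats, forms the null distribution of rate modulations (pooled across
    bins).  The latency is the left edge of the first post-onset bin whose
    actual baseline-subtracted rate exceeds the 95th (excitation) or falls
    below the 5th (inhibition) surrogate percentile for >= 2 consecutive
    bins within 200 ms of onset.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    spikes = np.asarray(spikes, float)
    onsets = np.asarray(onsets, float)
    bin_s = bin_ms / 1000.0
    n_pre = int(round(pre_s / bin_s))
    left_pre = np.arange(-n_pre, 0) * bin_s
    pre_counts = _bin_counts(spikes, onsets, left_pre, bin_s)  # (T, n_pre)
    pre_rates = pre_counts / bin_s

    T = len(onsets)
    offsets = rng.integers(0, n_pre, size=(n_surrogates, T))
    cols = (np.arange(n_pre)[None, None, :] - offsets[:, :, None]) % n_pre
    shifted = pre_rates[np.arange(T)[None, :, None], cols]  # (S, T, n_pre)
    surr_psth = shifted.mean(axis=1)  # (S, n_pre)
    half = n_pre // 2
    surr_mod = surr_psth[:, half:] - surr_psth[:, :half]  # (S, half)
    lo, hi = np.percentile(surr_mod, [100 - percentile, percentile])

    n_post = int(round(max_latency_ms / bin_ms)) + 1  # one extra for the pair rule
    left_post = np.arange(n_post) * bin_s
    post_counts = _bin_counts(spikes, onsets, left_post, bin_s)
    baseline = pre_rates[:, -int(round(PSTH_WINDOW_S / bin_s)):].mean()
    actual = post_counts.mean(axis=0) / bin_s - baseline

    above = actual > hi
    below = actual < lo
    for i in range(int(round(max_latency_ms / bin_ms))):
        if (above[i] and above[i + 1]) or (below[i] and below[i + 1]):
            return i * bin_ms
    return None
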