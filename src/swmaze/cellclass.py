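"""Waveform-based classification of units into putative pyramidal cells
(pPYR) and interneurons (pINT).

Two features of the mean extracellular waveform — half spike width (valley
width at half minimum) and valley-to-peak separation — are fit with a
two-component Gaussian mixture; the narrow-waveform component is labeled
pINT per the standard extracellular convention, and units with posterior
confidence below 0.95 stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = ["WaveformFeatures", "CellClass", "waveform_features",
           "classify_cells", "cell_class_table"]

CONFIDENCE_THRESHOLD = 0.95


@dataclass
class WaveformFeatures:
    unit: str
    half_width_ms: float | None
    valley_to_peak_ms: float | None

    @property
    def defined(self) -> bool:
        return self.half_width_ms is not None and self.valley_to_peak_ms is not None


@dataclass
class CellClass:
    unit: str
    label: str  # pPYR | pINT | unclassified
    confidence: float


def _cross_time(t: np.ndarray, y: np.ndarray, level: float, i0: int, i1: int,
                rising: bool) -> float | None:
    """Linear-interpolated time where y crosses level between i0 and i1."""
    seg = range(i0, i1) if rising else range(i1 - 1, i0 - 1, -1)
    for i in seg:
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            frac = (level - y0) / (y1 - y0)
            return t[i] + frac * (t[i + 1] - t[i])
    return None


def waveform_features(waveform: np.ndarray, fs: float,
                      unit: str = "") -> WaveformFeatures:
    """Half spike width and valley-to-peak separation (ms) of a mean waveform.

    The half width is the valley width at half the valley depth relative to
    the pre-spike baseline (mean of the first 20% of samples); the
    valley-to-peak time runs from the valley minimum to the subsequent
    maximum.  Both are amplitude-invariant.
    """
    wf = np.asarray(waveform, float)
    t_ms = np.arange(len(wf)) / fs * 1000.0
    n_base = max(1, len(wf) // 5)
    baseline = wf[:n_base].mean()
    i_valley = int(np.argmin(wf))
    depth = baseline - wf[i_valley]
    if depth <= 0 or np.ptp(wf) == 0:
        return WaveformFeatures(unit, None, None)
    level = baseline - depth / 2.0
    left = _cross_time(t_ms, wf, level, 0, i_valley, rising=False)
    right = _cross_time(t_ms, wf, level, i_valley, len(wf) - 1, rising=True)
    if left is None or right is None:
        return WaveformFeatures(unit, None, None)
    # positive peak after the valley; a waveform that never turns back up
    # within the window has no defined valley-to-peak time
    if i_valley >= len(wf) - 2:
        return WaveformFeatures(unit, None, None)
    post = wf[i_valley + 1:]
    i_peak = i_valley + 1 + int(np.argmax(post))
    if i_peak == len(wf) - 1 and wf[-1] < baseline:
        return WaveformFeatures(unit, None, None)
    return WaveformFeatures(unit, right - left, t_ms[i_peak] - t_ms[i_valley])


def classify_cells(features: list[WaveformFeatures],
                   seed: int = 0,
                   confidence: float = CONFIDENCE_THRESHOLD) -> list[CellClass]:
    """Two-component full-covariance Gaussian mixture over the feature plane.

    Initialization is deterministic: units are split at the median of their
    projection on the first principal axis of the standardized features, and
    the component means start at the two split means.  The component with
    the smaller mean (half width + valley-to-peak) is pINT.  Units with
    undefined features or posterior below ``confidence`` are unclassified.
    """
    defined = [f for f in features if f.defined]
    out = {f.unit: CellClass(f.unit, "unclassified", np.nan) for f in features}
    if len(defined) < 2:
        return [out[f.unit] for f in features]
    X = np.array([[f.half_width_ms, f.valley_to_peak_ms] for f in defined])
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    # first principal axis of the standardized cloud
    _, _, vt = np.linalg.svd(Xs - Xs.mean(axis=0), full_matrices=False)
    proj = Xs @ vt[0]
    split = proj >= np.median(proj)
    if split.all() or (~split).all():
        split[0] = ~split[0]
    means_init = np.vstack([X[~split].mean(axis=0), X[split].mean(axis=0)])
    gmm = GaussianMixture(n_components=2, covariance_type="full",
                          reg_covar=1e-6, means_init=means_init,
                          random_state=seed, n_init=1)
    gmm.fit(X)
    post = gmm.predict_proba(X)
    narrow = int(np.argmin(gmm.means_.sum(axis=1)))
    for f, pr in zip(defined, post):
        comp = int(np.argmax(pr))
        conf = float(pr[comp])
        label = "unclassified"
        if conf >= confidence:
            label = "pINT" if comp == narrow else "pPYR"
        out[f.unit] = CellClass(f.unit, label, conf)
    return [out[f.unit] for f in features]


def cell_class_table(features: list[WaveformFeatures],
                     classes: list[CellClass]) -> pd.DataFrame:
    return pd.DataFrame([
        {"unit": f.unit, "half_width_ms": f.half_width_ms,
         "valley_to_peak_ms": f.valley_to_peak_ms, "label": c.label,
         "confidence": c.confidence}
        for f, c in zip(features, classes)])
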