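"""LFP spectral analysis and spike-phase locking.

Morlet-wavelet power (1-100 Hz, 3-cycle wavelets), theta-band summaries,
instantaneous theta phase (4-12 Hz zero-phase FIR + Hilbert), and circular
statistics of spike phases (mean resultant length, Rayleigh test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import decimate, filtfilt, firwin, hilbert, fftconvolve

__all__ = ["Spectrogram", "PhaseLocking", "downsample_lfp",
           "morlet_spectrogram", "theta_power", "instantaneous_theta_phase",
           "phase_locking", "mean_resultant_length", "rayleigh_test"]

THETA_BAND = (4.0, 12.0)
LFP_FS = 2000.0
MIN_SPIKES = 30


def downsample_lfp(x: np.ndarray, fs: float, target_fs: float = LFP_FS) -> np.ndarray:
    """Anti-aliased decimation of a broadband trace to the analysis rate."""
    q = int(round(fs / target_fs))
    if q <= 1:
        return np.asarray(x, float)
    return decimate(np.asarray(x, float), q)


@dataclass
class Spectrogram:
    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray  # (n_freqs, n_times), |wavelet transform|

    def mean_power(self, time_mask: np.ndarray | None = None) -> np.ndarray:
        p = self.power if time_mask is None else self.power[:, time_mask]
        return p.mean(axis=1)


def morlet_spectrogram(x: np.ndarray, fs: float = LFP_FS,
                       freqs: np.ndarray | None = None,
                       n_cycles: float = 3.0) -> Spectrogram:
    """Morlet-wavelet amplitude per frequency and time.

    Each wavelet is a complex exponential under a Gaussian envelope with
    sigma_t = n_cycles / (2 pi f) (support about ``n_cycles`` cycles),
    L1-normalized so the response to a unit sinusoid is amplitude-like and
    scales linearly with the signal.
    """
    x = np.asarray(x, float)
    if freqs is None:
        freqs = np.arange(1.0, 101.0)
    freqs = np.asarray(freqs, float)
    f_min = freqs.min()
    if len(x) / fs < n_cycles / f_min:
        raise ValueError("trace shorter than the longest wavelet "
                         f"({n_cycles} cycles at {f_min} Hz)")
    power = np.empty((len(freqs), len(x)))
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(3 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        w = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / sigma_t) ** 2)
        w /= np.sum(np.abs(w))
        power[i] = np.abs(fftconvolve(x, w, mode="same"))
    return Spectrogram(freqs, np.arange(len(x)) / fs, power)


def theta_power(spec: Spectrogram, time_mask: np.ndarray | None = None,
                band: tuple[float, float] = THETA_BAND) -> float:
    """Mean power over the theta band within an epoch mask."""
    fm = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    return float(spec.mean_power(time_mask)[fm].mean())


def _theta_fir(fs: float, band: tuple[float, float]) -> np.ndarray:
    # kernel length: 3 cycles of the low cut, forced odd
    numtaps = int(round(3.0 / band[0] * fs))
    numtaps += 1 - numtaps % 2
    return firwin(numtaps, band, pass_zero=False, fs=fs)


def instantaneous_theta_phase(x: np.ndarray, fs: float = LFP_FS,
                              band: tuple[float, float] = THETA_BAND) -> np.ndarray:
    """Theta phase (rad, (-pi, pi]) of each LFP sample.

    Zero-phase band-pass (linear-phase FIR applied forward-backward), then
    the analytic-signal angle.  For a cosine carrier the extracted phase is
    the carrier phase; for a sine input, positive-going zero crossings map
    to -pi/2.
    """
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        raise ValueError("constant trace: phase undefined")
    taps = _theta_fir(fs, band)
    if len(x) <= 3 * len(taps):
        raise ValueError("trace shorter than filter transient")
    filtered = filtfilt(taps, [1.0], x)
    return np.angle(hilbert(filtered))


def mean_resultant_length(phases: np.ndarray) -> float:
    """MRL: magnitude of the mean unit phase vector, in [0, 1]."""
    phases = np.asarray(phases, float)
    if len(phases) == 0:
        raise ValueError("no phases")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns (Z, p).

    Z = n * MRL^2; p uses the standard series approximation
    ``exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``.
    """
    n = len(phases)
    R = mean_resultant_length(phases)
    Z = n * R * R
    p = np.exp(-Z) * (1 + (2 * Z - Z ** 2) / (4 * n)
                      - (24 * Z - 132 * Z ** 2 + 76 * Z ** 3 - 9 * Z ** 4)
                      / (288 * n ** 2))
    return float(Z), float(np.clip(p, 0.0, 1.0))


@dataclass
class PhaseLocking:
    status: str  # "ok" | "excluded"
    n_spikes: int
    mrl: float = np.nan
    rayleigh_z: float = np.nan
    p: float = np.nan
    significant: bool | None = None
    condition: str = ""

    def to_row(self, unit: str = "") -> dict:
        return {"unit": unit, "condition": self.condition,
                "n_spikes": self.n_spikes, "mrl": self.mrl,
                "rayleigh_p": self.p, "significant": self.significant}


def spike_phases(spike_times: np.ndarray, phase: np.ndarray, fs: float = LFP_FS,
                 t0: float = 0.0) -> np.ndarray:
    """Phase of the LFP sample closest in time to each spike.

    At 2 kHz the assignment error is below 0.25 ms, i.e. < 0.02 rad of a
    12 Hz oscillation, so no interpolation is needed.
    """
    idx = np.round((np.asarray(spike_times, float) - t0) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < len(phase))]
    return phase[idx]


def phase_locking(spike_times: np.ndarray, phase: np.ndarray,
                  epochs: list[tuple[float, float]] | None = None,
                  fs: float = LFP_FS, t0: float = 0.0,
                  min_spikes: int = MIN_SPIKES, alpha: float = 0.05,
                  condition: str = "") -> PhaseLocking:
    """MRL and Rayleigh test of spike theta phases within included epochs.

    Units with fewer than ``min_spikes`` spikes in the epochs are excluded
    (no p-value), keeping the phase estimate representative.
    """
    st = np.asarray(spike_times, float)
    if epochs is not None:
        keep = np.zeros(len(st), bool)
        for lo, hi in epochs:
            keep |= (st >= lo) & (st < hi)
        st = st[keep]
    ph = spike_phases(st, phase, fs, t0)
    if len(ph) < min_spikes:
        return PhaseLocking("excluded", len(ph), condition=condition)
    Z, p = rayleigh_test(ph)
    return PhaseLocking("ok", len(ph), mean_resultant_length(ph), Z, p,
                        p < alpha, condition)


def phase_locking_table(results: dict) -> pd.DataFrame:
    return pd.DataFrame([r.to_row(unit) for unit, r in results.items()])
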