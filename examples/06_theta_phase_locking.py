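"""Spike-LFP theta phase locking: MRL and the Rayleigh test.

A unit locked to theta with von-Mises concentration kappa = 2 at preferred
phase pi/4 is recovered from the LFP alone: band-pass the trace 4-12 Hz,
take the Hilbert phase at each spike, and compare the mean resultant
length against the closed form I1(2)/I0(2) = 0.698.
"""

import numpy as np

from swmaze import (instantaneous_theta_phase, mean_resultant_length,
                    phase_locking)
from swmaze.core import NeuronSpec
from swmaze.lfp import spike_phases
from swmaze.synth import generate_lfp, generate_spike_train, vonmises_mrl

fs, duration = 2000.0, 600.0
neuron = NeuronSpec(baseline_rate=10.0, theta_kappa=2.0, theta_mu=np.pi / 4)
t = np.arange(0, duration, 0.04)
spikes = generate_spike_train(neuron, t, np.zeros_like(t), theta_freq=8.0,
                              rng=np.random.default_rng(0))
lfp = generate_lfp(8.0, 1.0, 0.2, duration, fs, seed=1)

phase = instantaneous_theta_phase(lfp, fs)
res = phase_locking(spikes, phase, fs=fs)
mu_hat = np.angle(np.mean(np.exp(1j * spike_phases(spikes, phase, fs))))
print(f"n spikes: {res.n_spikes}")
print(f"MRL = {res.mrl:.3f} (closed form I1(2)/I0(2) = {vonmises_mrl(2.0):.3f})")
print(f"preferred phase = {mu_hat:.2f} rad (planted pi/4 = 0.79)")
print(f"Rayleigh p = {res.p:.2g} -> phase-locked: {res.significant}")
# MRL near 0.7 with a tiny Rayleigh p; an unlocked cell gives MRL near 0.
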