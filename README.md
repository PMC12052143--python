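# swmaze

Analysis pipeline for prefrontal single-unit and LFP recordings from a
delayed non-match-to-sample T-maze spatial-working-memory (SWM) task with
phase-specific optogenetic hippocampal silencing — together with a
synthetic-session generator that makes every stage of the analysis
verifiable against known ground truth.

It is written for systems neuroscientists who have sorted spike times,
tracked positions, trial/event records and an LFP trace per session, and
who want the full chain from raw tables to population statistics: behavior
scoring, linearized rate maps, Bayesian position decoding, goal-coding
analyses, optogenetic response characterization and theta phase-locking.
No real recordings ship with the package; the generator produces sessions
with planted tuning, goal gains, light effects and phase locking, so each
estimator can be tested against the parameters used to build its input.

## The models at the core

**Inhomogeneous-Poisson session generator.** Each synthetic unit fires with
rate

λ(t) = f(pos(t)) · g_goal(t) · ℓ_light(t) · exp(κ cos(θ(t) − μ)) / I₀(κ),

where `f` is a positional tuning curve (e.g. a Gaussian place field),
`g_goal` a multiplicative gain on the preferred goal arm, `ℓ_light` a step
(optionally with onset latency and exponential time constant) inside light
pulses, and the last factor von-Mises phase coupling to an 8 Hz theta
carrier in the LFP. Spikes are drawn by thinning; the von-Mises kernel
gives the closed-form recovery oracle MRL = I₁(κ)/I₀(κ).

**Rate maps and spatial information.** Linearized rate maps are
spikes/occupancy per position bin, restricted to running (speed ≥ 5 cm/s).
Spatial information per spike is Skaggs'
`SI = Σᵢ pᵢ (fᵢ/f̄) log₂(fᵢ/f̄)` with occupancy probabilities pᵢ and
occupancy-weighted mean rate f̄.

**Bayesian position decoder.** With independent Poisson units and a uniform
prior, `P(pos|n) ∝ Πᵢ (τ fᵢ(pos))^{nᵢ} e^{−τ fᵢ(pos)}` over 10 cm bins,
evaluated in the log domain on overlapping 125 ms windows stepped by 25 ms;
the decoded position is the posterior argmax.

**Goal coding.** Side-separated rates over 20 cm bins (10 cm overlap), an
at-goal rate (speed ≤ 5 cm/s within 5 cm of the goal), a goal × position
ANOVA (selective if p < 0.025 in either light condition), and the goal
index `(f_pref − f_nonpref)/(f_pref + f_nonpref)` per position. A
standardized linear SVM with paired-resampling leave-one-pair-out
cross-validation decodes the visited goal arm per position bin.

**Light responses.** Units are excited/inhibited when the 0.5 s post-onset
rate differs from the 0.5 s baseline (Wilcoxon signed-rank, p < 0.05);
response latency is the first post-onset 10 ms bin whose baseline-subtracted
rate beats the 5th/95th percentile of 1000 circular-shift surrogates for
two consecutive bins within 200 ms.

**LFP.** Morlet-wavelet power (1–100 Hz, 3-cycle wavelets), theta (4–12 Hz)
band summaries, instantaneous theta phase via zero-phase FIR + Hilbert, and
spike-phase statistics (mean resultant length, Rayleigh `Z = nR²`).

## Worked example

```python
import numpy as np
from swmaze import (generate_session, segment_trajectories,
                    track_from_session, cross_validated_decoding)
from swmaze.core import NeuronSpec, SessionConfig, gaussian_field

neurons = [NeuronSpec(baseline_rate=0.5,
                      tuning=gaussian_field(80 * i / 24, 6.0, 25.0))
           for i in range(25)]
session = generate_session(SessionConfig(n_trials=40, seed=2,
                                         include_lfp=False), neurons=neurons)
track = track_from_session(session)
segments = segment_trajectories(session, track)
res = cross_validated_decoding(session, track, segments, "sample", False)
print(res.mean_error_cm, res.percent_correct)
```

prints

```
2.8866405860079003 84.97899159663865
```

— 25 place cells tiling the 80 cm track decode the animal's position with a
mean error of 2.9 cm, and 85% of 125 ms windows land in exactly the right
10 cm bin (chance is 12.5%). The same session run through the shuffled
control (`shuffle_rng=...`) drops to ~13–15%, confirming the accuracy comes
from tuning, not from occupancy structure. See `examples/` for one short
script per capability (behavior scoring, rate maps, position decoding, goal
coding, light-response latency, phase locking, the full pipeline runner).

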