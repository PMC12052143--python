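# Methods

This note documents the models, estimators and design choices in `swmaze`:
what the synthetic-session generator emulates, how each analysis stage is
defined, the tunable parameters with their defaults, and the limits of what
passing tests on synthetic data can show about real recordings.

## Task and geometry

A session is a sequence of delayed non-match-to-sample trials on a T-maze.
Linearized position `d` measures distance (cm) from the stem start: the
start box occupies `d < 0` (default extent 16 cm), the stem `0–40 cm`, and
either goal arm `40–80 cm`; left/right identity travels in a separate arm
label so that both arms share one positional axis ("position relative to
the goal"). Each trial has a sample phase (forced run to a pseudorandomly
chosen arm), a 15 s delay confined to the start box, and a choice phase in
which the opposite arm is rewarded; `correct ⇔ choice ≠ sample`. Light is
delivered in 50% of trials, restricted to one configured phase, with equal
left/right sample goals inside each light condition (this balance forces
`n_trials` divisible by 4 at the default 0.5 light probability).

## Synthetic sessions

The generator is the package's ground-truth instrument; its defaults are
the study conditions (40 trials, 15 s delay, 25 Hz position sampling,
2 kHz LFP, 8 Hz theta). Where the protocol leaves quantities unspecified
we chose once: running speed is piecewise-constant per run at
`N(30, 5) cm/s` (floored at 8), goal dwells are uniform 1–3 s (long enough
to create the ≤5 cm/s at-goal epochs the goal analyses need), start-box
dwells 1 s, and the inter-trial interval is shortened to 2 s because no
analysis consumes it. Position samples get 0.02 cm Gaussian jitter during
runs only, keeping stationary epochs genuinely below the speed threshold.

Spike trains are inhomogeneous Poisson, drawn by thinning from

```
lambda(t) = spatial(pos(t)) * goal_gain(t) * light(t)
            * exp(kappa * cos(theta(t) - mu)) / I0(kappa)
```

* `spatial` = baseline + tuning curve, evaluated per trajectory type
  (tuning may differ by phase and running direction); negative composite
  rates are a hard error, not clipped silently.
* `goal_gain` multiplies the rate whenever the animal is on the preferred
  goal arm (`d > 40` with the matching arm label).
* `light` is 1 outside pulses; inside, after a configurable onset latency,
  it ramps to `1 + sign·magnitude` with exponential time constant
  (default 5 ms; 0 gives a pure step). Light and theta factors are
  evaluated exactly at candidate spike times rather than on the 25 Hz
  position grid, so planted latencies are sharp at the millisecond scale.
* Theta coupling uses a **von-Mises kernel**, not a raised cosine: the
  spike-phase density is then exactly von-Mises with concentration κ, whose
  mean resultant length is I₁(κ)/I₀(κ) in closed form. A `1 + m·cos`
  modulation was considered and rejected because its spike-phase MRL is
  m/2, capped at 0.5 — it cannot represent strong locking (κ = 2 implies
  MRL ≈ 0.70) and admits no exact recovery oracle.

All randomness flows from one session seed through named substreams
(trials, trajectory, per-unit spikes, LFP), so adding a neuron never
changes the trial plan or trajectory, and identical inputs give
byte-identical sessions.

`replace_spikes_in_phase` regenerates spikes inside selected trial phases
(e.g. only light-on sample phases) from replacement neuron specs, holding
the trajectory and all other spikes fixed. This is how condition-specific
perturbations — remapped place fields, reduced goal gains — are planted to
emulate a silencing effect on tuning itself.

The LFP is a cosine theta carrier plus white noise. The cosine convention
matters: the instantaneous phase extracted downstream (4–12 Hz zero-phase
FIR, forward–backward, then Hilbert angle) equals the generative phase, so
planted preferred phases are recovered without offset. For a sine input
the extracted phase at positive-going zero crossings is −π/2, which is the
documented convention of the phase estimator.

### What the generator does not emulate

Real PFC data have spike-sorting contamination, non-Poisson firing
(bursting, refractoriness), theta frequency drift and phase precession,
behavioral idiosyncrasies (head scans, variable paths), and light-artifact
transients. Passing recovery tests here therefore shows the estimators are
correct for their stated statistical model, not that the model captures
every property of tissue recordings.

## Behavior

Speed is `|Δd|/Δt` (unsigned, so the ≥5 cm/s running filter is
direction-agnostic), with the first sample copied from the second and an
optional 3-sample median filter (default on, recorded in provenance).
2-D positions are linearized by projection onto the nearest track segment
with a 10 cm off-track gate; flagged samples are excluded from occupancy
and spike assignment alike, preserving the rate = spikes/time contract.
Trajectories are segmented per phase into one outbound run (start-box exit
at `d = 0` to goal arrival at `d ≥ 75`), at-goal epochs (speed ≤ 5 cm/s
within 5 cm of the goal), and one inbound run (goal departure to start-box
entry). Phases where the goal is never reached yield an incomplete
outbound segment that downstream stages drop.

## Rate maps and statistics

Bins are half-open `[lo, hi)` with the final bin closed; with overlapping
bins every sample and spike is credited to each containing bin, and
occupancy is counted per bin independently. Per-trial maps stay
unsmoothed; averaged maps pool spikes and occupancy across trials, and the
10 cm running-average smoothing (for 1 cm-bin correlation analyses) uses a
shrinking window at track ends rather than padding, ignoring missing bins.

The spatial-modulation test is a one-way repeated-measures ANOVA with
trials as subjects, `F = MS_position / MS_(position×trial)`. Trials missing
any bin after speed filtering are dropped (complete-case), keeping the
balanced design the RM-ANOVA requires; zero within-position variance with
nonzero position variance is reported as significant with p → 0. Its
type-I rate is calibrated at ~5% on untuned Poisson cells and its power
exceeds 80% for a planted 10→2 Hz field with 20 trials.

Spatial information follows the occupancy-weighted per-spike form; silent
cells are undefined and raise rather than returning 0, mirroring the ≥1 Hz
unit-inclusion convention. Map similarity is Pearson r over bins present
in both maps (NaN if either map is flat), with an even/odd split variant
for within-condition stability.

## Position decoding

The decoder is Poisson naive Bayes over 10 cm bins with a uniform prior, a
0.01 Hz rate floor (the factorial term cancels in the normalized
posterior), spike counts in 125 ms windows advancing 25 ms, and
lowest-index argmax tie-breaking. A window's true position is the
linearized position at its center; windows below the speed threshold are
excluded. "Correct" means the decoded bin is exactly the bin containing
the true position — the strictest reading of percent-correct. Sessions
need > 10 simultaneous units. Leave-one-trial-out training pools spikes
and occupancy of all other trials of the same condition;
`train_off_test_on` fits all light-off trials at once and decodes each
light-on trial. The chance control permutes each held-out trial's count
vectors across its windows, severing the count–position relation while
keeping both marginals; this lands at ~100/n_bins for a near-uniform
traversal, whereas permuting training maps across bins turned out to
inherit occupancy structure and is not used.

## Goal coding and goal decoding

The selectivity test is a goal × position ANOVA on three per-trial summary
bins (outbound goal-arm 40–80 cm average, at-goal rate, inbound average),
run separately per light condition; a unit is goal-selective at p < 0.025
(the two-condition Bonferroni threshold, taken as given) in either
condition. The preferred goal is determined from light-off trials only, so
light effects are always measured against an unperturbed reference. The
goal index is computed per position along the unfolded axis (outbound 20 cm
bins, the at-goal point, inbound bins in traversal order); `0/0` is a
missing value, never 0.

Goal decoding standardizes features per training fold and uses a linear
max-margin classifier (SVC, C = 1). Per repeat, `n_pairs` left/right trial
pairs (10 for sample, 8 for choice) are drawn without replacement and
cross-validated leave-one-pair-out; accuracies average over folds then
repeats (default 100; the pipeline and tests use 10–20 for speed, stated
in their configs). Significance against 50% uses a one-proportion z-test
on pooled fold-level counts with Bonferroni correction over bins — the
pooled choice is one reading of an ambiguous replication unit and is
flagged here deliberately. Bins a trial never occupied contribute 0 Hz
(no spikes observed), which only matters for rarely-visited bins.

## Light responses

Classification compares per-pulse rates 0.5 s post vs 0.5 s pre onset
(Wilcoxon signed-rank, zeros dropped); direction is the sign of the mean
difference, percent change is relative to the pre-onset baseline, and a
silent baseline leaves percent change undefined. Latency surrogates
circularly shift each pulse's 1 s pre-onset 10 ms rate vector by an
independent uniform offset (preserving the rate marginal and
autocorrelation), average across pulses, and take second-half minus
first-half differences; 1000 repeats pooled across bins give one global
pair of 5th/95th percentile thresholds. The latency is the left edge of
the first post-onset bin beyond threshold for ≥ 2 consecutive bins in the
same direction within 200 ms; otherwise absent. Pooling percentiles across
bins (rather than per-bin thresholds) is the documented resolution of an
ambiguity in the procedure's description.

## LFP and phase locking

Morlet wavelets use σ_t = n_cycles/(2πf) with n_cycles = 3 (support about
three cycles), L1-normalized so responses scale linearly with signal
amplitude; power is the transform modulus. The theta band-pass FIR spans
3 cycles of the 4 Hz low cut (0.75 s at 2 kHz, odd length) and is applied
forward–backward for zero phase. Spikes take the phase of the nearest LFP
sample — at 2 kHz the assignment error is < 0.25 ms, i.e. < 0.02 rad at
12 Hz, so interpolation is unnecessary. Phase-locking requires ≥ 30 spikes
per condition; the Rayleigh p uses the standard series approximation in
`Z = nR²` and n, which the tests hold within 0.01 of a Monte-Carlo null at
n = 50.

## Cell classification

Waveform features are the valley width at half depth relative to the
pre-spike baseline (mean of the first 20% of samples) and the
valley-to-peak time; both are amplitude-invariant. A two-component
full-covariance Gaussian mixture (EM, ridge 1e-6) is initialized
deterministically by splitting units at the median projection onto the
first principal axis of the standardized features, making refits
reproducible. The narrower component is labeled pINT per the standard
extracellular convention; posteriors below 0.95 stay unclassified.

## Statistical utilities

Fisher's exact test is two-sided by the point-probability rule (the sum of
same-margin tables no more probable than the observed one); a zero margin
returns p = 1 by convention. The signed-rank test drops zero differences
and uses the exact null for n ≤ 25 without ties, otherwise the
tie-corrected normal approximation; the rank-sum test is exact for
untied samples up to n = 25 per group. These wrap scipy's implementations
behind the package's edge-case contracts and are cross-checked in the
tests against brute-force enumeration oracles.

## Problem sizes and determinism

The reference experiments (`swmaze.experiments`) use 40-trial sessions
with 18–100 units, 2000 simulated cells for ANOVA calibration (large
enough that Monte-Carlo noise in a ~5% rate is ~0.5 points), 50 runs for
latency recovery, 10⁴ spikes for MRL calibration, and 20 SVM repeats for
goal decoding; the full pipeline demo uses a 20-unit, 40-trial session and
completes in well under a minute on one CPU. Every experiment takes an
explicit seed, all generation flows through named substreams, and pipeline
reruns with identical configs produce byte-identical tables.

## Known limitations

* The generator's trajectory model is deliberately schematic (constant
  speed per run, no 2-D dynamics beyond the embedding used for
  linearization round-trips).
* The RM-ANOVA drops trials with missing bins rather than interpolating;
  with very sparse occupancy this can discard many trials.
* The goal decoder fills never-occupied bins with 0 Hz rather than
  imputing.
* The z-test's replication unit for goal decoding pools fold-level counts,
  which is anticonservative if folds are correlated across repeats; the
  per-bin accuracies themselves are unaffected.
* Brief-light sessions model foraging as statistically uniform baseline
  firing; no open-field place structure is simulated.
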