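"""Synthetic session generator.

Produces complete sessions of the delayed non-match-to-sample T-maze task
with known ground truth: T-maze trajectories (start box -> stem -> goal arm
and back, with delay confinement), spatially tuned and goal-selective
inhomogeneous-Poisson spiking, light-evoked rate changes with controlled
sign/magnitude/latency, and a theta-band LFP to which spikes can be
von-Mises phase-locked.  Every downstream analysis stage is validated
against sessions from this module.

All randomness flows from a single session seed through named substreams
(trials, trajectory, per-unit spikes, LFP), so adding a neuron never
perturbs the trial structure or the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0, i1

from .core import (
    ARM_LEFT,
    ARM_RIGHT,
    ARM_STARTBOX,
    ARM_STEM,
    LEFT,
    RIGHT,
    STREAM_LFP,
    STREAM_SPIKES,
    STREAM_TRAJECTORY,
    STREAM_TRIALS,
    MazeGeometry,
    NeuronSpec,
    Session,
    SessionConfig,
    TrialRecord,
    other_side,
    substream,
)

__all__ = [
    "generate_session",
    "generate_spike_train",
    "generate_lfp",
    "generate_brief_light_session",
    "replace_spikes_in_phase",
    "draw_trial_plan",
    "vonmises_mrl",
    "make_waveform",
    "BriefLightSession",
]


def vonmises_mrl(kappa: float) -> float:
    """Mean resultant length of a von-Mises distribution: I1(kappa)/I0(kappa).

    This is the closed-form recovery oracle for phase-locked spiking: the
    generator modulates the rate by ``exp(kappa*cos(theta - mu)) / I0(kappa)``
    (time-averaged factor 1 over a uniform phase), so the spike-phase density
    is exactly von-Mises and the empirical MRL converges to this value.  A
    plain ``1 + m*cos`` modulation cannot express strong locking (its MRL is
    capped at 0.5), hence the von-Mises kernel.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def draw_trial_plan(config: SessionConfig, rng: np.random.Generator | None = None):
    """Draw (sample_goal, light_on, correct) for each trial.

    Light trials are chosen pseudorandomly at ``p_light`` with equal numbers
    of left and right sample goals within each light condition; errors occur
    independently with probability ``p_error``.
    """
    if rng is None:
        rng = substream(config.seed, STREAM_TRIALS)
    n = config.n_trials
    n_on = int(round(n * config.p_light))
    for count, name in ((n_on, "light-on"), (n - n_on, "light-off")):
        if count % 2:
            raise ValueError(f"cannot balance goals: odd number of {name} trials")
    light = np.array([True] * n_on + [False] * (n - n_on))
    goals = np.empty(n, dtype="U1")
    for cond in (True, False):
        idx = np.flatnonzero(light == cond)
        half = len(idx) // 2
        g = np.array([LEFT] * half + [RIGHT] * half)
        rng.shuffle(g)
        goals[idx] = g
    order = rng.permutation(n)
    light, goals = light[order], goals[order]
    errors = rng.random(n) < config.p_error
    plan = []
    for i in range(n):
        sample = goals[i]
        choice = sample if errors[i] else other_side(sample)
        plan.append((sample, choice, bool(light[i])))
    return plan


class _Trajectory:
    """Incrementally built position series with per-sample metadata."""

    def __init__(self, rate: float):
        self.dt = 1.0 / rate
        self.t: list[np.ndarray] = []
        self.d: list[np.ndarray] = []
        self.phase: list[np.ndarray] = []
        self.direction: list[np.ndarray] = []
        self.goal: list[np.ndarray] = []
        self._n = 0

    @property
    def now(self) -> float:
        return self._n * self.dt

    def append(self, d: np.ndarray, phase: str, direction: str, goal: str) -> None:
        n = len(d)
        if n == 0:
            return
        t = (self._n + np.arange(n)) * self.dt
        self.t.append(t)
        self.d.append(np.asarray(d, float))
        self.phase.append(np.full(n, phase, dtype="U6"))
        self.direction.append(np.full(n, direction, dtype="U10"))
        self.goal.append(np.full(n, goal, dtype="U1"))
        self._n += n

    def hold(self, d0: float, duration: float, phase: str, goal: str) -> None:
        n = max(1, int(round(duration / self.dt)))
        self.append(np.full(n, d0), phase, "stationary", goal)

    def run(self, d0: float, d1: float, speed: float, phase: str, goal: str,
            jitter_cm: float, rng: np.random.Generator) -> None:
        duration = abs(d1 - d0) / speed
        n = max(2, int(round(duration / self.dt)))
        d = np.linspace(d0, d1, n, endpoint=False)
        if jitter_cm > 0:
            d = d + rng.normal(0.0, jitter_cm, n)
        self.append(d, phase, "outbound" if d1 > d0 else "inbound", goal)

    def arrays(self):
        return (np.concatenate(self.t), np.concatenate(self.d),
                np.concatenate(self.phase), np.concatenate(self.direction),
                np.concatenate(self.goal))


def _arm_labels(d: np.ndarray, goal: np.ndarray, geometry: MazeGeometry) -> np.ndarray:
    arm = np.full(len(d), ARM_STEM, dtype="U10")
    arm[d < 0] = ARM_STARTBOX
    on_arm = d > geometry.stem_length
    arm[on_arm & (goal == LEFT)] = ARM_LEFT
    arm[on_arm & (goal == RIGHT)] = ARM_RIGHT
    return arm


def generate_session(config: SessionConfig, geometry: MazeGeometry | None = None,
                     neurons: list[NeuronSpec] | None = None) -> Session:
    """Generate a full synthetic session (trajectory, spikes, LFP, events).

    Deterministic: the same (config, geometry, neurons) yields a bit-identical
    session.  With ``p_error = 0`` every trial is correct, and left/right
    sample goals are balanced within each light condition.
    """
    if geometry is None:
        geometry = MazeGeometry()
    if neurons is None:
        neurons = []
    if config.n_trials < 2:
        raise ValueError("need at least 2 trials")

    plan = draw_trial_plan(config)
    traj_rng = substream(config.seed, STREAM_TRAJECTORY)
    traj = _Trajectory(config.position_rate)

    d_box = -geometry.start_box_extent / 2.0
    d_goalstop = geometry.track_max - 1.0  # dwell point, within 5 cm of the goal
    trials: list[TrialRecord] = []
    light_events: list[tuple[float, float, str]] = []

    def draw_speed() -> float:
        return max(8.0, traj_rng.normal(config.mean_speed, config.speed_jitter))

    for i, (sample_goal, choice_goal, light_on) in enumerate(plan):
        bounds: dict[str, tuple[float, float]] = {}
        traj.hold(d_box, config.startbox_dwell_s, "iti", "")
        goal_departures: dict[str, float] = {}
        for phase, goal in (("sample", sample_goal), ("choice", choice_goal)):
            t0 = traj.now
            traj.run(d_box, geometry.track_max, draw_speed(), phase, goal,
                     config.position_jitter_cm, traj_rng)
            dwell = traj_rng.uniform(*config.goal_dwell_range)
            traj.hold(d_goalstop, dwell, phase, goal)
            goal_departures[phase] = traj.now
            traj.run(d_goalstop, d_box, draw_speed(), phase, goal,
                     config.position_jitter_cm, traj_rng)
            traj.hold(d_box, config.startbox_dwell_s, phase, goal)
            bounds[phase] = (t0, traj.now)
            if phase == "sample":
                t0d = traj.now
                traj.hold(d_box, config.delay_s, "delay", "")
                bounds["delay"] = (t0d, traj.now)
        traj.hold(d_box, config.iti_s, "iti", "")
        # re-order bounds dict to task order
        bounds = {p: bounds[p] for p in ("sample", "delay", "choice")}
        trials.append(TrialRecord(i, sample_goal, choice_goal, light_on, bounds))
        if light_on and config.light_phase != "none":
            lo, hi = bounds[config.light_phase]
            if config.light_phase == "choice":
                hi = goal_departures["choice"]  # light off once the return starts
            light_events.append((lo, hi, config.light_phase))

    pos_t, pos_d, phase_lab, direction, run_goal = traj.arrays()
    arm = _arm_labels(pos_d, run_goal, geometry)
    duration = pos_t[-1] + traj.dt

    lfp = None
    if config.include_lfp:
        lfp = generate_lfp(config.theta_freq, config.lfp_amplitude,
                           config.lfp_noise_sd, duration, config.lfp_rate,
                           rng=substream(config.seed, STREAM_LFP))

    light_iv = [(a, b) for a, b, _ in light_events]
    spikes: dict[str, np.ndarray] = {}
    waveforms: dict[str, np.ndarray] = {}
    for j, spec in enumerate(neurons):
        unit = f"u{j:03d}"
        rng = substream(config.seed, STREAM_SPIKES, j)
        spikes[unit] = generate_spike_train(
            spec, pos_t, pos_d,
            phase=phase_lab, direction=direction, goal_side=run_goal,
            geometry=geometry, light_intervals=light_iv,
            theta_freq=config.theta_freq, rng=rng)
        waveforms[unit] = make_waveform(spec.cell_type, rng=rng)

    session = Session(
        geometry=geometry, config=config, trials=trials,
        pos_t=pos_t, pos_d=pos_d, pos_arm=arm,
        spikes=spikes, light_events=light_events, lfp=lfp,
        waveforms=waveforms,
        ground_truth={
            "neurons": neurons,
            "plan": plan,
            "theta_freq": config.theta_freq,
            "phase_label": phase_lab,
            "direction": direction,
            "run_goal": run_goal,
        },
    )
    session.validate()
    return session


def _light_factor(t: np.ndarray, intervals, effect) -> np.ndarray:
    out = np.ones(len(t))
    if effect.sign == 0 or effect.magnitude == 0 or not intervals:
        return out
    for onset, offset in intervals:
        inside = (t >= onset) & (t < offset)
        if np.any(inside):
            out[inside] = effect.factor(t[inside] - onset)
    return out


def generate_spike_train(spec: NeuronSpec, t: np.ndarray, d: np.ndarray, *,
                         phase: np.ndarray | None = None,
                         direction: np.ndarray | None = None,
                         goal_side: np.ndarray | None = None,
                         geometry: MazeGeometry | None = None,
                         light_intervals=(),
                         theta_freq: float = 0.0,
                         theta_phase0: float = 0.0,
                         rng: np.random.Generator | None = None,
                         seed: int | None = None) -> np.ndarray:
    """Inhomogeneous-Poisson spike train by thinning.

    The rate is ``lambda(t) = spatial(pos(t)) * goal_gain(t) * light(t) *
    exp(kappa*cos(theta(t) - theta_mu)) / I0(kappa)``, so the spike-phase
    distribution is exactly von-Mises with concentration ``theta_kappa``.
    The spatial/goal part is evaluated on the position samples and linearly
    interpolated; light and theta factors are evaluated exactly at candidate
    spike times, so planted latencies are sharp at millisecond resolution.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    if len(t) == 0:
        return np.array([])
    if geometry is None:
        geometry = MazeGeometry()
    n = len(t)
    if phase is None:
        phase = np.full(n, "sample", dtype="U6")
    if direction is None:
        direction = np.full(n, "outbound", dtype="U10")
    if goal_side is None:
        goal_side = np.full(n, "", dtype="U1")

    lam = np.empty(n)
    for ph in np.unique(phase):
        for di in np.unique(direction):
            m = (phase == ph) & (direction == di)
            if np.any(m):
                lam[m] = spec.spatial_rate(d[m], str(ph), str(di))
    if spec.preferred_goal is not None and spec.goal_gain != 1.0:
        on_pref = (goal_side == spec.preferred_goal) & (d > geometry.stem_length)
        lam[on_pref] *= spec.goal_gain
    if np.any(lam < 0):
        raise ValueError("negative rate after composition")

    kappa = spec.theta_kappa if theta_freq > 0 else 0.0
    theta_peak = float(np.exp(kappa) / i0(kappa)) if kappa > 0 else 1.0
    exc = 1.0 + spec.light.magnitude if spec.light.sign > 0 else 1.0
    lam_max = lam.max() * theta_peak * exc
    if lam_max <= 0:
        return np.array([])

    t0, t1 = t[0], t[-1]
    n_cand = rng.poisson(lam_max * (t1 - t0))
    if n_cand == 0:
        return np.array([])
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    rate = np.interp(cand, t, lam)
    rate = rate * _light_factor(cand, light_intervals, spec.light)
    if kappa > 0:
        theta = 2 * np.pi * theta_freq * cand + theta_phase0
        rate = rate * np.exp(kappa * np.cos(theta - spec.theta_mu)) / i0(kappa)
    keep = rng.random(n_cand) < rate / lam_max
    return cand[keep]


def generate_lfp(theta_freq: float, amplitude: float, noise_sd: float,
                 duration: float, rate: float,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None, phase0: float = 0.0) -> np.ndarray:
    """Theta-band LFP: a cosine carrier plus white noise.

    The carrier is ``amplitude * cos(2 pi f t + phase0)``, so the instantaneous
    phase extracted downstream (band-pass + Hilbert) equals the generative
    theta phase used for spike phase-locking.
    """
    if rate < 2 * theta_freq:
        raise ValueError("sampling rate below Nyquist for requested theta frequency")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = amplitude * np.cos(2 * np.pi * theta_freq * t + phase0)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x


def replace_spikes_in_phase(session: Session, specs: list[NeuronSpec],
                            phase: str = "sample", light_on: bool = True,
                            seed: int = 0) -> Session:
    """Regenerate spikes inside selected trial phases from new neuron specs.

    Spikes within the ``phase`` windows of trials with the given light flag
    are redrawn from ``specs`` (one per unit, in unit order); all other
    spikes, the trajectory, events and LFP are untouched.  This plants
    condition-specific perturbations — remapped fields or reduced goal
    gains in light-on trials — with everything else held fixed, emulating a
    selective optogenetic effect on the underlying tuning.
    """
    gt = session.ground_truth
    windows = [tr.phase_bounds[phase] for tr in session.trials
               if tr.light_on == light_on]
    units = session.units
    if len(specs) != len(units):
        raise ValueError("need one replacement spec per unit")
    new_spikes = {}
    for j, u in enumerate(units):
        st = session.spikes[u]
        keep = np.ones(len(st), bool)
        for lo, hi in windows:
            keep &= ~((st >= lo) & (st < hi))
        pieces = [st[keep]]
        rng = substream(seed, 97, j)
        for lo, hi in windows:
            m = (session.pos_t >= lo) & (session.pos_t < hi)
            pieces.append(generate_spike_train(
                specs[j], session.pos_t[m], session.pos_d[m],
                phase=gt["phase_label"][m], direction=gt["direction"][m],
                goal_side=gt["run_goal"][m], geometry=session.geometry,
                theta_freq=session.config.theta_freq, rng=rng))
        new_spikes[u] = np.sort(np.concatenate(pieces))
    return Session(
        geometry=session.geometry, config=session.config,
        trials=session.trials, pos_t=session.pos_t, pos_d=session.pos_d,
        pos_arm=session.pos_arm, spikes=new_spikes,
        light_events=session.light_events, lfp=session.lfp,
        waveforms=session.waveforms, waveform_fs=session.waveform_fs,
        ground_truth={**gt, "replaced": (phase, light_on)})


@dataclass
class BriefLightSession:
    """Open-field session with brief light pulses (no maze, no task)."""

    spikes: dict[str, np.ndarray]
    light_onsets: np.ndarray
    pulse_s: float
    duration: float
    ground_truth: dict = field(default_factory=dict)


def generate_brief_light_session(neurons: list[NeuronSpec], n_pulses: int = 150,
                                 pulse_s: float = 0.5, iti_s: float = 3.0,
                                 pre_s: float = 2.0, seed: int = 0) -> BriefLightSession:
    """Brief-light protocol: pulses of ``pulse_s`` separated by ``iti_s``.

    Units fire at their baseline rate (the animal forages in a small box, so
    no spatial structure is modeled) and respond to light per their
    ``LightEffect``.
    """
    onsets = pre_s + np.arange(n_pulses) * (pulse_s + iti_s)
    duration = onsets[-1] + pulse_s + iti_s
    intervals = [(o, o + pulse_s) for o in onsets]
    t = np.linspace(0.0, duration, max(2, int(duration * 25)))
    d = np.zeros_like(t)
    spikes = {}
    for j, spec in enumerate(neurons):
        rng = substream(seed, STREAM_SPIKES, j)
        spikes[f"u{j:03d}"] = generate_spike_train(
            spec, t, d, phase=np.full(len(t), "sample", dtype="U6"),
            light_intervals=intervals, rng=rng)
    return BriefLightSession(spikes, onsets, pulse_s, duration,
                             {"neurons": neurons})


def make_waveform(cell_type: str = "pyr", fs: float = 32000.0,
                  rng: np.random.Generator | None = None,
                  n_samples: int = 64) -> np.ndarray:
    """Mean extracellular waveform template (negative valley, later peak).

    Putative pyramidal cells get a broad valley and long valley-to-peak time;
    putative interneurons a narrow valley and short valley-to-peak.  Small
    per-unit jitter keeps the feature clouds realistic for mixture fitting.
    """
    if cell_type == "int":
        width_ms, v2p_ms = 0.14, 0.28
    else:
        width_ms, v2p_ms = 0.32, 0.75
    if rng is not None:
        width_ms *= rng.normal(1.0, 0.08)
        v2p_ms *= rng.normal(1.0, 0.08)
    t = (np.arange(n_samples) - n_samples // 3) / fs * 1000.0  # ms, valley at 0
    sigma_v = width_ms / 2.355  # FWHM -> SD
    wf = -np.exp(-0.5 * (t / sigma_v) ** 2)
    wf += 0.35 * np.exp(-0.5 * ((t - v2p_ms) / (sigma_v * 2.2)) ** 2)
    return wf
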