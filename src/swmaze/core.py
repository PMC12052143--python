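"""Core data types shared across the pipeline.

Conventions used throughout the package: time in seconds, positions in cm,
rates in Hz.  Linearized position ``d`` measures distance from the start of
the central stem: negative values are in the start box, 0-40 cm on the stem,
40-80 cm on either goal arm (left/right identity is carried by an arm label,
not by the coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

LEFT = "L"
RIGHT = "R"
SIDES = (LEFT, RIGHT)
PHASES = ("sample", "delay", "choice")

ARM_STARTBOX = "startbox"
ARM_STEM = "stem"
ARM_LEFT = "left_goal"
ARM_RIGHT = "right_goal"


def other_side(side: str) -> str:
    return RIGHT if side == LEFT else LEFT


@dataclass(frozen=True)
class MazeGeometry:
    """Linearized T-maze geometry.

    The track spans ``[-start_box_extent, stem_length + goal_arm_length]``;
    the goal (reward port) sits at the far end of each goal arm.
    """

    stem_length: float = 40.0
    goal_arm_length: float = 40.0
    start_box_extent: float = 16.0

    def __post_init__(self) -> None:
        if min(self.stem_length, self.goal_arm_length, self.start_box_extent) <= 0:
            raise ValueError("all maze lengths must be positive")

    @property
    def track_min(self) -> float:
        return -self.start_box_extent

    @property
    def track_max(self) -> float:
        return self.stem_length + self.goal_arm_length

    @property
    def goal_position(self) -> float:
        return self.track_max


@dataclass(frozen=True)
class LightEffect:
    """Light-evoked multiplicative rate change.

    Inside a pulse, after an onset latency, the firing rate is multiplied by
    ``1 + sign * magnitude * (1 - exp(-dt / tau))``; ``tau_ms = 0`` gives a
    pure step.  ``sign = 0`` or ``magnitude = 0`` means no effect.
    """

    sign: int = 0
    magnitude: float = 0.0
    latency_ms: float = 0.0
    tau_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError("sign must be -1, 0 or +1")
        if self.magnitude < 0:
            raise ValueError("magnitude is a fractional change >= 0")
        if self.sign < 0 and self.magnitude > 1:
            raise ValueError("suppression beyond 100% would give negative rates")

    def factor(self, dt_since_onset: np.ndarray) -> np.ndarray:
        """Rate factor for times ``dt_since_onset`` (s) inside a pulse."""
        dt = np.asarray(dt_since_onset, dtype=float) - self.latency_ms / 1000.0
        if self.tau_ms > 0:
            ramp = 1.0 - np.exp(-np.clip(dt, 0, None) / (self.tau_ms / 1000.0))
        else:
            ramp = (dt >= 0).astype(float)
        ramp = np.where(dt < 0, 0.0, ramp)
        return 1.0 + self.sign * self.magnitude * ramp


# A tuning function maps linearized position (cm) to firing rate above
# baseline (Hz).  NeuronSpec.tuning may be a single callable (applied to all
# trajectories) or a mapping keyed by (phase, direction) with optional
# "default" entry, where direction is "outbound" or "inbound".
Tuning = Callable[[np.ndarray], np.ndarray]


def gaussian_field(center: float, sigma: float, peak: float) -> Tuning:
    """Gaussian place field on the linearized track (peak Hz above baseline)."""

    def f(d: np.ndarray) -> np.ndarray:
        return peak * np.exp(-0.5 * ((np.asarray(d, float) - center) / sigma) ** 2)

    return f


@dataclass
class NeuronSpec:
    """Ground-truth generative parameters of one synthetic unit."""

    baseline_rate: float = 1.0
    tuning: Tuning | Mapping[object, Tuning] | None = None
    goal_gain: float = 1.0
    preferred_goal: str | None = None
    light: LightEffect = field(default_factory=LightEffect)
    theta_kappa: float = 0.0
    theta_mu: float = 0.0
    cell_type: str = "pyr"  # "pyr" or "int"; only sets the waveform template

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.goal_gain < 0:
            raise ValueError("goal_gain must be >= 0")
        if self.theta_kappa < 0:
            raise ValueError("theta_kappa must be >= 0")
        if self.preferred_goal is not None and self.preferred_goal not in SIDES:
            raise ValueError("preferred_goal must be 'L' or 'R'")

    def tuning_for(self, phase: str, direction: str) -> Tuning | None:
        if self.tuning is None or callable(self.tuning):
            return self.tuning
        for key in ((phase, direction), "default"):
            if key in self.tuning:
                return self.tuning[key]
        return None

    def spatial_rate(self, d: np.ndarray, phase: str, direction: str) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        rate = np.full(d.shape, float(self.baseline_rate))
        tun = self.tuning_for(phase, direction)
        if tun is not None:
            add = np.asarray(tun(d), dtype=float)
            if np.any(rate + add < -1e-9):
                raise ValueError("tuning produces negative expected rates")
            rate = rate + add
        return np.clip(rate, 0.0, None)


@dataclass
class TrialRecord:
    """One delayed non-match-to-sample trial.

    ``correct`` is true iff the choice arm differs from the sample arm
    (non-match rule).
    """

    index: int
    sample_goal: str
    choice_goal: str
    light_on: bool
    phase_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def correct(self) -> bool:
        return self.choice_goal != self.sample_goal

    def goal_for(self, phase: str) -> str:
        return self.sample_goal if phase == "sample" else self.choice_goal


@dataclass
class SessionConfig:
    """Knobs of the synthetic session generator.

    Defaults mirror the task protocol: 40 trials per session, light delivered
    in 50% of trials (chosen pseudorandomly with equal left/right sample goals
    in each light condition), a 15 s delay, position tracking at 25 Hz and
    LFP at 2 kHz.
    """

    n_trials: int = 40
    p_error: float = 0.0
    light_phase: str = "sample"  # sample | delay | choice | none
    p_light: float = 0.5
    delay_s: float = 15.0
    mean_speed: float = 30.0  # cm/s, per-run piecewise constant
    speed_jitter: float = 5.0  # SD of per-run speed (cm/s)
    goal_dwell_range: tuple[float, float] = (1.0, 3.0)
    startbox_dwell_s: float = 1.0
    iti_s: float = 2.0
    position_rate: float = 25.0
    lfp_rate: float = 2000.0
    theta_freq: float = 8.0
    lfp_amplitude: float = 1.0
    lfp_noise_sd: float = 0.2
    position_jitter_cm: float = 0.02
    include_lfp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_error <= 1.0:
            raise ValueError("p_error must lie in [0, 1]")
        if self.n_trials % 2:
            raise ValueError("n_trials must be even for balanced goals")
        if self.light_phase not in PHASES + ("none",):
            raise ValueError(f"unknown light_phase {self.light_phase!r}")


@dataclass
class Session:
    """A complete (synthetic or loaded) recording session."""

    geometry: MazeGeometry
    config: SessionConfig
    trials: list[TrialRecord]
    pos_t: np.ndarray  # (n,) sample times, s
    pos_d: np.ndarray  # (n,) linearized position, cm
    pos_arm: np.ndarray  # (n,) arm labels (str)
    spikes: dict[str, np.ndarray]  # unit id -> sorted spike times
    light_events: list[tuple[float, float, str]]  # (onset, offset, phase)
    lfp: np.ndarray | None = None  # sampled at config.lfp_rate starting at t=0
    waveforms: dict[str, np.ndarray] = field(default_factory=dict)
    waveform_fs: float = 32000.0
    ground_truth: dict = field(default_factory=dict)

    @property
    def units(self) -> list[str]:
        return sorted(self.spikes)

    @property
    def duration(self) -> float:
        return float(self.pos_t[-1]) if len(self.pos_t) else 0.0

    def validate(self) -> None:
        for unit, st in self.spikes.items():
            if len(st) > 1 and not np.all(np.diff(st) > 0):
                raise ValueError(f"spike times of unit {unit} not strictly increasing")
        for tr in self.trials:
            bounds = [tr.phase_bounds[p] for p in PHASES if p in tr.phase_bounds]
            for (a0, a1), (b0, b1) in zip(bounds[:-1], bounds[1:]):
                if not (a0 < a1 <= b0 < b1):
                    raise ValueError(f"trial {tr.index}: phases overlap or out of order")
        for onset, offset, phase in self.light_events:
            if not onset < offset:
                raise ValueError("light event with non-positive duration")


def substream(seed: int, *key: int) -> np.random.Generator:
    """Named random substream: same (seed, key) always yields the same stream.

    Used so that e.g. adding a neuron draws from new spike streams without
    perturbing the trial or trajectory streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# substream key codes
STREAM_TRIALS = 1
STREAM_TRAJECTORY = 2
STREAM_LFP = 3
STREAM_SPIKES = 4  # (STREAM_SPIKES, unit_index)
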