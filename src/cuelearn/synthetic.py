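"""Synthetic cohort generator.

Produces complete synthetic sessions — shot outcomes, full-body joint-angle
kinematics and paired real/virtual validation angles — with the statistical
structure the downstream analysis assumes:

* absolute directional error follows an exponentially decaying mean curve
  toward an asymptote, with additive Gaussian motor noise;
* intertrial noise is constant across trials in the default ("evr") preset
  and decays in the "real_world" preset;
* joint angular-velocity profiles are smooth unimodal bumps whose amplitudes
  trend over trials: right-shoulder channels shrink while the right-elbow
  internal/external-rotation channel grows.

All numeric defaults below (noise SDs, tolerance, time constants, bump
amplitudes) are artifact defaults chosen to produce the qualitative structure
above; they are not measured values from any study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .kinematics import JointAngleRecording
from .performance import ShotOutcome

#: Body segments tracked by a 17-IMU full-body suit, one triplet of Euler
#: DoF each: Z (flexion/extension), X (abduction/adduction),
#: Y (internal/external rotation).
SEGMENTS: tuple[str, ...] = (
    "pelvis",
    "torso",
    "sternum",
    "neck",
    "head",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
)

DOF_SUFFIXES: tuple[str, ...] = ("z", "x", "y")

#: Channels whose bump amplitude decays over trials.
SHOULDER_CHANNELS: tuple[str, ...] = (
    "right_shoulder_z",
    "right_shoulder_x",
    "right_shoulder_y",
)

#: Channel whose bump amplitude grows over trials.
ELBOW_ROTATION_CHANNEL: str = "right_elbow_y"


def channel_names() -> list[str]:
    """The 51 channel names (17 segments x 3 DoF), `<segment>_<dof>`."""
    return [f"{seg}_{dof}" for seg in SEGMENTS for dof in DOF_SUFFIXES]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters for a synthetic cohort.

    Counts must be positive and SDs non-negative; ``seed`` fixes every source
    of randomness (per-subject streams are derived from it, so generation is
    deterministic and independent of subject order).
    """

    n_subjects: int = 10
    n_trials: int = 300
    block_size: int = 25
    kinematics_rate: float = 60.0
    n_channels: int = 51
    trial_duration: float = 3.0
    error_asymptote: float = 4.0
    error_amplitude_mean: float = 8.3
    error_amplitude_sd: float = 2.47
    error_decay_tau: float = 60.0
    motor_noise_sd: float = 7.0
    success_tolerance: float = 5.0
    seed: int = 0
    #: If set, per-trial noise SD decays from motor_noise_sd toward this value
    #: with time constant noise_decay_tau (the "real_world" preset).
    motor_noise_sd_final: float | None = None
    noise_decay_tau: float | None = None
    #: 0.0 -> per-subject random sign on the mean curve; nonzero -> that sign.
    direction_bias: float = 0.0
    include_kinematics: bool = True
    # kinematic bump parameters (deg/s amplitudes, seconds for times/widths)
    peak_time: float = 1.5
    bump_width: float = 0.25
    shoulder_amp_start: float = 40.0
    shoulder_amp_end: float = 24.0
    elbow_rot_amp_start: float = 10.0
    elbow_rot_amp_end: float = 26.0
    baseline_amp: float = 6.0
    kin_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_trials", "block_size", "n_channels"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.kinematics_rate <= 0:
            raise ConfigurationError("kinematics_rate must be positive")
        if self.trial_duration <= 0:
            raise ConfigurationError("trial_duration must be positive")
        for name in ("error_amplitude_sd", "motor_noise_sd", "kin_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_channels != len(SEGMENTS) * len(DOF_SUFFIXES):
            raise ConfigurationError(
                f"n_channels must be {len(SEGMENTS) * len(DOF_SUFFIXES)} "
                f"(17 segments x 3 DoF), got {self.n_channels}"
            )


def evr_preset(**overrides) -> CohortConfig:
    """Default preset: constant intertrial motor noise across all trials."""
    return CohortConfig(**overrides)


def real_world_preset(**overrides) -> CohortConfig:
    """Contrast preset: motor noise decays over the session."""
    params = dict(motor_noise_sd=9.0, motor_noise_sd_final=4.0, noise_decay_tau=80.0)
    params.update(overrides)
    return CohortConfig(**params)


@dataclass(frozen=True)
class GeneratorTruth:
    """Noiseless curve parameters for one subject; reconstructs the mean curve."""

    amplitude: float
    asymptote: float
    tau: float
    sign: float
    noise_sd_start: float
    noise_sd_final: float | None
    noise_tau: float | None

    def mean_curve(self, n_trials: int) -> np.ndarray:
        """Noiseless |error| curve at trials 0..n_trials-1."""
        t = np.arange(n_trials, dtype=float)
        return self.asymptote + self.amplitude * np.exp(-t / self.tau)

    def noise_sd(self, n_trials: int) -> np.ndarray:
        t = np.arange(n_trials, dtype=float)
        if self.noise_sd_final is None or self.noise_tau is None:
            return np.full(n_trials, self.noise_sd_start)
        return self.noise_sd_final + (self.noise_sd_start - self.noise_sd_final) * np.exp(
            -t / self.noise_tau
        )


@dataclass
class SyntheticSession:
    subject_id: str
    outcomes: list[ShotOutcome]
    kinematics: list[JointAngleRecording]
    generator_truth: GeneratorTruth


@dataclass(frozen=True)
class StageParams:
    """Per-channel velocity-bump parameters for a single trial."""

    amplitudes: np.ndarray  # (n_channels,), deg/s
    peak_time: float  # s
    width: float  # s

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("bump width must be positive")


def stage_params_for_trial(trial_index: int, config: CohortConfig) -> StageParams:
    """Bump amplitudes for one trial, with shoulder-down / elbow-rotation-up trends."""
    frac = trial_index / max(config.n_trials - 1, 1)
    names = channel_names()
    amps = np.full(len(names), config.baseline_amp)
    sh = config.shoulder_amp_start + (config.shoulder_amp_end - config.shoulder_amp_start) * frac
    el = config.elbow_rot_amp_start + (config.elbow_rot_amp_end - config.elbow_rot_amp_start) * frac
    for i, name in enumerate(names):
        if name in SHOULDER_CHANNELS:
            amps[i] = sh
        elif name == ELBOW_ROTATION_CHANNEL:
            amps[i] = el
    return StageParams(amplitudes=amps, peak_time=config.peak_time, width=config.bump_width)


def generate_trial_kinematics(
    trial_index: int,
    config: CohortConfig,
    stage_params: StageParams | None = None,
    rng: np.random.Generator | None = None,
) -> JointAngleRecording:
    """One trial's joint-angle recording whose velocity is a Gaussian bump.

    The angle series is the running integral of
    ``amplitude * exp(-(t - peak_time)^2 / (2 width^2)) + noise`` per channel,
    so finite differencing downstream recovers the bump (analytic peak
    location: ``peak_time``).
    """
    if config.kinematics_rate <= 0:
        raise ConfigurationError("kinematics_rate must be positive")
    if stage_params is None:
        stage_params = stage_params_for_trial(trial_index, config)
    if rng is None:
        rng = np.random.default_rng([config.seed, trial_index])
    rate = config.kinematics_rate
    n = int(round(config.trial_duration * rate))
    time = np.arange(n) / rate
    bump = np.exp(-((time - stage_params.peak_time) ** 2) / (2 * stage_params.width**2))
    velocity = bump[:, None] * stage_params.amplitudes[None, :]
    if config.kin_noise_sd > 0:
        velocity = velocity + rng.normal(0.0, config.kin_noise_sd, velocity.shape)
    angles = np.cumsum(velocity, axis=0) / rate
    return JointAngleRecording(
        time=time, angles=angles, rate=rate, channel_names=channel_names()
    )


def _subject_rng(config: CohortConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, subject_index])


def generate_session(subject_index: int, config: CohortConfig) -> SyntheticSession:
    """Generate one subject's session (outcomes + optional kinematics)."""
    rng = _subject_rng(config, subject_index)
    amplitude = max(0.0, rng.normal(config.error_amplitude_mean, config.error_amplitude_sd))
    if config.direction_bias != 0.0:
        sign = float(np.sign(config.direction_bias))
    else:
        sign = float(rng.choice([-1.0, 1.0]))
    truth = GeneratorTruth(
        amplitude=amplitude,
        asymptote=config.error_asymptote,
        tau=config.error_decay_tau,
        sign=sign,
        noise_sd_start=config.motor_noise_sd,
        noise_sd_final=config.motor_noise_sd_final,
        noise_tau=config.noise_decay_tau,
    )
    mean = truth.mean_curve(config.n_trials)
    sd = truth.noise_sd(config.n_trials)
    noise = rng.normal(0.0, 1.0, config.n_trials) * sd
    direction = sign * mean + noise
    abs_error = np.abs(direction)
    success = abs_error <= config.success_tolerance
    outcomes = [
        ShotOutcome(trial=t, direction=float(direction[t]), abs_error=float(abs_error[t]),
                    success=bool(success[t]))
        for t in range(config.n_trials)
    ]
    kinematics: list[JointAngleRecording] = []
    if config.include_kinematics:
        for t in range(config.n_trials):
            kinematics.append(
                generate_trial_kinematics(t, config, stage_params_for_trial(t, config), rng)
            )
    return SyntheticSession(
        subject_id=f"S{subject_index:02d}",
        outcomes=outcomes,
        kinematics=kinematics,
        generator_truth=truth,
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticSession]:
    """Generate all subjects' sessions. Deterministic given ``config.seed``."""
    return [generate_session(i, config) for i in range(config.n_subjects)]


def expected_block_reduction(truth: GeneratorTruth, n_trials: int, block_size: int) -> float:
    """Noiseless first-block-mean minus last-full-block-mean |error|."""
    curve = truth.mean_curve(n_trials)
    n_blocks = n_trials // block_size
    first = curve[:block_size].mean()
    last = curve[(n_blocks - 1) * block_size : n_blocks * block_size].mean()
    return float(first - last)


def generate_validation_pairs(
    n_shots: int,
    angle_range: tuple[float, float] = (-50.0, 50.0),
    discrepancy_sd: float = 2.85,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Paired (real_angle, virtual_angle) shots, shape (n_shots, 2), degrees.

    Real angles are uniform on ``angle_range``; virtual = real + zero-mean
    Gaussian noise of SD ``discrepancy_sd``.
    """
    lo, hi = angle_range
    if n_shots <= 0:
        raise ConfigurationError("n_shots must be positive")
    if discrepancy_sd < 0:
        raise ConfigurationError("discrepancy_sd must be >= 0")
    if not hi > lo:
        raise ConfigurationError(f"empty angle range [{lo}, {hi}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    real = rng.uniform(lo, hi, n_shots)
    virtual = real + rng.normal(0.0, discrepancy_sd, n_shots)
    return np.column_stack([real, virtual])
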