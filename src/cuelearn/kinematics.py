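"""Joint-angle preprocessing: angular velocity, trial peak, peak-centred window.

Works on velocity rather than raw angles because velocities are insensitive to
constant sensor offsets (drift); see the invariance test in the suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import BoundaryError, InsufficientDataError, SamplingError, SchemaError

#: Segments whose DoFs define the trial peak (mean absolute velocity).
FOCUS_SEGMENTS: tuple[str, ...] = ("right_shoulder", "right_elbow")

_JITTER_TOL = 1e-6  # s


@dataclass
class JointAngleRecording:
    """One trial's joint-angle time series.

    ``angles`` is (n_samples, n_channels) in degrees; ``channel_names`` are
    ``<segment>_<dof>`` with dof in {z, x, y}.
    """

    time: np.ndarray
    angles: np.ndarray
    rate: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[0] != self.time.shape[0]:
            raise SchemaError("angles must be (n_samples, n_channels) matching time")
        if len(self.channel_names) != self.angles.shape[1]:
            raise SchemaError("channel_names length must match angle columns")
        if self.rate <= 0:
            raise SamplingError("rate must be positive")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise SamplingError(f"non-monotone timestamps at row {row}")
            if np.ptp(dt) > _JITTER_TOL:
                raise SamplingError("non-uniform sampling beyond 1e-6 s jitter")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[0]


@dataclass
class TrialKinematics:
    """Velocity matrix plus the peak-aligned 1-second analysis window."""

    velocity: np.ndarray  # (n_samples, n_channels), deg/s
    rate: float
    peak_index: int
    window: np.ndarray  # (round(rate)+1, n_channels)


def angular_velocity(rec: JointAngleRecording) -> np.ndarray:
    """Angular velocity (deg/s) by central differences, one-sided at the edges."""
    if rec.n_samples < 3:
        raise InsufficientDataError("need >= 3 samples to differentiate")
    return np.gradient(rec.angles, axis=0) * rec.rate


def focus_channel_indices(
    names: Sequence[str], focus_segments: Sequence[str] = FOCUS_SEGMENTS
) -> list[int]:
    idx = [i for i, n in enumerate(names) if n.rsplit("_", 1)[0] in focus_segments]
    if len(idx) != 3 * len(focus_segments):
        raise SchemaError(
            f"expected {3 * len(focus_segments)} focus channels for {focus_segments}, "
            f"found {len(idx)}"
        )
    return idx


def find_trial_peak(
    vel: np.ndarray,
    names: Sequence[str],
    focus_segments: Sequence[str] = FOCUS_SEGMENTS,
) -> int:
    """Index of the maximum of mean |velocity| over the focus-segment DoFs."""
    idx = focus_channel_indices(names, focus_segments)
    profile = np.mean(np.abs(vel[:, idx]), axis=1)
    return int(np.argmax(profile))


def window_half_width(rate: float) -> int:
    return int(round(rate)) // 2


def crop_peak_window(vel: np.ndarray, peak: int, rate: float) -> np.ndarray:
    """Symmetric window of round(rate)+1 samples centred on ``peak``.

    Raises BoundaryError if the window would exceed the recording; trials are
    flagged rather than padded (padding would distort covariance metrics).
    """
    half = window_half_width(rate)
    lo, hi = peak - half, peak + half
    if lo < 0 or hi >= vel.shape[0]:
        raise BoundaryError(
            f"peak {peak} too close to edge for a {2 * half + 1}-sample window "
            f"in a {vel.shape[0]}-sample trial"
        )
    return vel[lo : hi + 1]


def prepare_trial(
    rec: JointAngleRecording, focus_segments: Sequence[str] = FOCUS_SEGMENTS
) -> TrialKinematics:
    """velocity -> peak -> window, the full per-trial preprocessing chain."""
    vel = angular_velocity(rec)
    peak = find_trial_peak(vel, rec.channel_names, focus_segments)
    window = crop_peak_window(vel, peak, rec.rate)
    return TrialKinematics(velocity=vel, rate=rec.rate, peak_index=peak, window=window)
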