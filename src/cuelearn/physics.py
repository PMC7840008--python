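"""2D billiards shot physics and motion-capture -> virtual frame calibration.

Strike estimation follows the engine rule: the collision input is the median
velocity and direction of the cue stick over the 10 rendering frames before
contact. Ball-ball contact transfers the line-of-centers velocity component
with a restitution parameter (default e=1: full transfer for equal masses —
a literal "sticking" collision could not produce a separately travelling
target ball, so the idealized transfer is used and the wording is recorded
here as an open question). Friction is uniform deceleration; spin, cushion
rebounds and 3D effects are out of scope. Integration stops once all ball
speeds fall below a threshold. The stop threshold, friction, masses, radii
and table dimensions are artifact defaults, not measured engine values.

Angle convention: 0 deg points along +y (straight toward the far cushion);
positive angles turn leftward (+x to the left).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InsufficientDataError,
    ResolutionError,
)
from .performance import ShotOutcome, signed_directional_error

VR_FRAME_RATE = 90.0  # Hz
STRIKE_FRAMES = 10  # frames (~0.11 s at 90 Hz) used for the median
BALL_RADIUS = 0.0286  # m


@dataclass(frozen=True)
class TableGeometry:
    """Table rectangle [0, width] x [0, length] with corner pockets."""

    length: float = 2.24
    width: float = 1.12
    pocket_positions: tuple[tuple[float, float], ...] = ()
    pocket_radius: float = 0.07
    cue_start: tuple[float, float] = (0.56, 0.56)
    target_start: tuple[float, float] = (0.56, 1.40)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ConfigurationError("table dimensions must be positive")
        if self.pocket_radius <= 0:
            raise ConfigurationError("pocket_radius must be positive")
        if not self.pocket_positions:
            corners = (
                (0.0, 0.0),
                (self.width, 0.0),
                (0.0, self.length),
                (self.width, self.length),
            )
            object.__setattr__(self, "pocket_positions", corners)
            # containment check only applies to the default axis-aligned frame;
            # custom pockets allow rotated/translated table frames
            for p in (self.cue_start, self.target_start):
                if not (0 <= p[0] <= self.width and 0 <= p[1] <= self.length):
                    raise ConfigurationError(f"start point {p} outside table")

    @property
    def far_left_pocket(self) -> tuple[float, float]:
        # far = max y; left = min x under the leftward-positive convention
        return max(self.pocket_positions, key=lambda p: (p[1], -p[0]))


@dataclass(frozen=True)
class PhysicsParams:
    friction_decel: float = 0.3  # m/s^2
    restitution: float = 1.0
    stop_threshold: float = 0.01  # m/s
    dt: float = 1.0 / 360.0  # s
    ball_radius: float = BALL_RADIUS

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction_decel <= 0 or self.stop_threshold <= 0:
            raise ConfigurationError("dt, friction_decel, stop_threshold must be positive")
        if not 0.0 <= self.restitution <= 1.0:
            raise ConfigurationError("restitution must be in [0, 1]")


@dataclass
class CueSampleStream:
    """Cue-tip positions sampled at the VR frame rate."""

    timestamps: np.ndarray
    tip_positions: np.ndarray  # (n, 2)
    frame_rate: float = VR_FRAME_RATE

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.tip_positions = np.asarray(self.tip_positions, dtype=float)
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ConfigurationError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class StrikeEstimate:
    speed: float
    direction: tuple[float, float]  # unit vector

    @property
    def velocity(self) -> np.ndarray:
        return self.speed * np.asarray(self.direction)


@dataclass
class ContactInfo:
    """Diagnostics recorded at the ball-ball contact instant."""

    time: float
    normal: np.ndarray  # unit line-of-centers vector, cue -> target
    v_cue_pre: np.ndarray
    v_cue_post: np.ndarray
    v_target_post: np.ndarray


@dataclass
class ShotTrajectory:
    times: np.ndarray
    cue_path: np.ndarray  # (n, 2)
    target_path: np.ndarray  # (n, 2)
    outcome: ShotOutcome
    contact: ContactInfo | None = None


@dataclass(frozen=True)
class FrameTransform:
    """Planar similarity (rotation + uniform scale + translation) plus a
    linear height ratio for the vertical axis."""

    rotation: float  # rad
    scale: float
    translation: tuple[float, float]
    height_ratio: float

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.height_ratio <= 0:
            raise ConfigurationError("scale and height_ratio must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def inverse(self) -> "FrameTransform":
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        inv_rot = -self.rotation
        inv_scale = 1.0 / self.scale
        tx, ty = self.translation
        # p = s R q + t  =>  q = (1/s) R^-1 (p - t)
        it = inv_scale * np.array([[c, s], [-s, c]]) @ np.array([-tx, -ty])
        return FrameTransform(
            rotation=inv_rot,
            scale=inv_scale,
            translation=(float(it[0]), float(it[1])),
            height_ratio=1.0 / self.height_ratio,
        )


def angle_to_unit(angle_deg: float) -> np.ndarray:
    """Unit vector for the documented convention (0 deg = +y, positive left)."""
    rad = math.radians(angle_deg)
    return np.array([-math.sin(rad), math.cos(rad)])


def estimate_strike(stream: CueSampleStream, contact_time: float) -> StrikeEstimate:
    """Strike speed/direction from the componentwise-median cue velocity over
    the STRIKE_FRAMES frames preceding contact.

    Per-frame velocities are finite differences of tip positions; the speed is
    the magnitude of the median vector and the direction its unit vector.
    """
    mask = stream.timestamps <= contact_time
    idx = np.nonzero(mask)[0]
    if idx.size < STRIKE_FRAMES + 1:
        raise InsufficientDataError(
            f"need >= {STRIKE_FRAMES + 1} samples before contact, got {idx.size}"
        )
    sel = idx[-(STRIKE_FRAMES + 1) :]
    pos = stream.tip_positions[sel]
    dt = np.diff(stream.timestamps[sel])[:, None]
    velocities = np.diff(pos, axis=0) / dt  # (STRIKE_FRAMES, 2)
    median_v = np.median(velocities, axis=0)
    speed = float(np.linalg.norm(median_v))
    if speed == 0.0:
        return StrikeEstimate(speed=0.0, direction=(0.0, 1.0))
    d = median_v / speed
    return StrikeEstimate(speed=speed, direction=(float(d[0]), float(d[1])))


def _decelerate(v: np.ndarray, decel: float, dt: float) -> np.ndarray:
    speed = np.linalg.norm(v)
    if speed == 0.0:
        return v
    new_speed = max(0.0, speed - decel * dt)
    return v * (new_speed / speed)


def _segment_sphere_contact(
    p_rel: np.ndarray, v_rel: np.ndarray, dt: float, contact_dist: float
) -> float | None:
    """First time in [0, dt] at which |p_rel + t v_rel| == contact_dist
    (swept-circle test; avoids tunneling). None if no contact this step."""
    a = float(v_rel @ v_rel)
    if a == 0.0:
        return None
    b = 2.0 * float(p_rel @ v_rel)
    c = float(p_rel @ p_rel) - contact_dist**2
    if c <= 0.0:  # already overlapping: treat as immediate contact
        return 0.0
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    t = (-b - math.sqrt(disc)) / (2 * a)
    if 0.0 <= t <= dt:
        return t
    return None


def simulate_shot(
    strike: StrikeEstimate,
    table: TableGeometry,
    params: PhysicsParams | None = None,
    max_time: float = 30.0,
    aim_pocket: Sequence[float] | None = None,
) -> ShotTrajectory:
    """Integrate a shot: cue ball launched with the strike velocity, uniform
    friction deceleration, line-of-centers transfer at ball-ball contact,
    termination when all speeds drop below the stop threshold.

    Success = the target ball path enters any pocket radius; the outcome's
    directional error is measured against the far-left pocket.
    """
    if params is None:
        params = PhysicsParams()
    dt = params.dt
    contact_dist = 2.0 * params.ball_radius
    # tunneling guard: one step should not cross more than half the contact distance
    if strike.speed * dt > 0.5 * contact_dist and strike.speed > 0:
        raise ResolutionError(
            f"dt={dt} too coarse for speed {strike.speed:.3f} m/s "
            f"(step exceeds half the contact distance)"
        )
    cue = np.asarray(table.cue_start, dtype=float).copy()
    tgt = np.asarray(table.target_start, dtype=float).copy()
    v_cue = strike.velocity.astype(float)
    v_tgt = np.zeros(2)
    times = [0.0]
    cue_path = [cue.copy()]
    tgt_path = [tgt.copy()]
    collided = False
    contact_info: ContactInfo | None = None
    t = 0.0
    n_steps = int(math.ceil(max_time / dt))
    for _ in range(n_steps):
        if np.linalg.norm(v_cue) < params.stop_threshold and np.linalg.norm(
            v_tgt
        ) < params.stop_threshold:
            break
        if not collided:
            tc = _segment_sphere_contact(cue - tgt, v_cue - v_tgt, dt, contact_dist)
            if tc is not None:
                cue = cue + v_cue * tc
                tgt = tgt + v_tgt * tc
                n = tgt - cue
                norm = np.linalg.norm(n)
                if norm == 0.0:
                    raise ResolutionError("coincident ball centers at contact")
                n = n / norm
                v_rel_n = float((v_cue - v_tgt) @ n)
                v_cue_pre = v_cue.copy()
                if v_rel_n > 0:
                    # equal masses: impulse (1+e)/2 of the normal relative speed
                    j = 0.5 * (1.0 + params.restitution) * v_rel_n
                    v_cue = v_cue - j * n
                    v_tgt = v_tgt + j * n
                collided = True
                contact_info = ContactInfo(
                    time=t + tc,
                    normal=n.copy(),
                    v_cue_pre=v_cue_pre,
                    v_cue_post=v_cue.copy(),
                    v_target_post=v_tgt.copy(),
                )
                remaining = dt - tc
                cue = cue + v_cue * remaining
                tgt = tgt + v_tgt * remaining
                v_cue = _decelerate(v_cue, params.friction_decel, dt)
                v_tgt = _decelerate(v_tgt, params.friction_decel, dt)
                t += dt
                times.append(t)
                cue_path.append(cue.copy())
                tgt_path.append(tgt.copy())
                continue
        cue = cue + v_cue * dt
        tgt = tgt + v_tgt * dt
        v_cue = _decelerate(v_cue, params.friction_decel, dt)
        v_tgt = _decelerate(v_tgt, params.friction_decel, dt)
        t += dt
        times.append(t)
        cue_path.append(cue.copy())
        tgt_path.append(tgt.copy())
    cue_arr = np.array(cue_path)
    tgt_arr = np.array(tgt_path)
    pocket = np.asarray(
        table.far_left_pocket if aim_pocket is None else aim_pocket, dtype=float
    )
    pockets = np.asarray(table.pocket_positions, dtype=float)
    dists = np.linalg.norm(tgt_arr[:, None, :] - pockets[None, :, :], axis=2)
    success = bool(np.any(dists <= table.pocket_radius))
    try:
        signed = signed_directional_error(
            tgt_arr, table.target_start, pocket, min_displacement=1e-9
        )
        abs_err = abs(signed)
    except Exception:
        signed, abs_err = float("nan"), float("nan")
    outcome = ShotOutcome(
        trial=0,
        direction=signed if np.isfinite(signed) else 0.0,
        abs_error=abs_err if np.isfinite(abs_err) else 0.0,
        success=success,
    )
    return ShotTrajectory(
        times=np.array(times),
        cue_path=cue_arr,
        target_path=tgt_arr,
        outcome=outcome,
        contact=contact_info,
    )


def fit_frame_transform(
    mocap_xy: np.ndarray,
    virtual_xy: np.ndarray,
    mocap_heights: Sequence[float] | None = None,
    virtual_heights: Sequence[float] | None = None,
) -> FrameTransform:
    """Least-squares planar similarity transform from >= 2 landmark
    correspondences, plus a least-squares linear height ratio.

    The calibration protocol places markers in the table's corner pockets and
    one on the cue-ball spot (5 correspondences); only 2 non-coincident points
    are strictly required.
    """
    src = np.asarray(mocap_xy, dtype=float)
    dst = np.asarray(virtual_xy, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise DegenerateGeometryError("landmark arrays must be matching (n, 2)")
    if src.shape[0] < 2:
        raise DegenerateGeometryError("need >= 2 correspondences")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    var_src = float(np.sum(src_c**2))
    if var_src == 0.0:
        raise DegenerateGeometryError("coincident source landmarks")
    # complex least squares: dst ~ z * src with z = scale * e^{i rot}
    zs = src_c[:, 0] + 1j * src_c[:, 1]
    zd = dst_c[:, 0] + 1j * dst_c[:, 1]
    z = np.vdot(zs, zd) / np.vdot(zs, zs)
    scale = float(abs(z))
    if scale == 0.0:
        raise DegenerateGeometryError("degenerate correspondence (zero scale)")
    rotation = float(np.angle(z))
    rot_mat = scale * np.array(
        [[math.cos(rotation), -math.sin(rotation)], [math.sin(rotation), math.cos(rotation)]]
    )
    translation = dst.mean(axis=0) - rot_mat @ src.mean(axis=0)
    if mocap_heights is not None and virtual_heights is not None:
        hm = np.asarray(mocap_heights, dtype=float)
        hv = np.asarray(virtual_heights, dtype=float)
        denom = float(hm @ hm)
        height_ratio = float(hm @ hv) / denom if denom > 0 else 1.0
        if height_ratio <= 0:
            height_ratio = 1.0
    else:
        height_ratio = 1.0
    return FrameTransform(
        rotation=rotation,
        scale=scale,
        translation=(float(translation[0]), float(translation[1])),
        height_ratio=height_ratio,
    )


def apply_transform(t: FrameTransform, point: Sequence[float]) -> np.ndarray:
    """Map a 3D point (x, y_plane, height): plane rotated/scaled/translated,
    height multiplied by the height ratio. 2D points are mapped in-plane."""
    p = np.asarray(point, dtype=float)
    planar = t.matrix @ p[:2] + np.asarray(t.translation)
    if p.size == 2:
        return planar
    return np.array([planar[0], planar[1], p[2] * t.height_ratio])
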