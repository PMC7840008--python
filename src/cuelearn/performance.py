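"""Task-space learning measures: directional error, blocks, success rate,
robust intertrial variability (t-distribution scale) and its learning-corrected
variant (scale of residuals from a within-block linear trend)."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import BallNotMovedError, ConfigurationError, UndefinedMetricError

DEFAULT_BLOCK_SIZE = 25
DF_MIN, DF_MAX = 1.0, 100.0
_MAD_TO_SD = 1.482602218505602  # 1/Phi^-1(3/4)


@dataclass(frozen=True)
class ShotOutcome:
    """One trial's result: signed direction (deg, relative to the desired
    direction), absolute error, and pocket-success flag."""

    trial: int
    direction: float
    abs_error: float
    success: bool

    def __post_init__(self) -> None:
        if self.abs_error < 0:
            raise ConfigurationError("abs_error must be >= 0")


@dataclass
class Block:
    index: int
    outcomes: list[ShotOutcome]
    is_partial: bool = False

    @property
    def n(self) -> int:
        return len(self.outcomes)

    @property
    def directions(self) -> np.ndarray:
        return np.array([o.direction for o in self.outcomes])

    @property
    def abs_errors(self) -> np.ndarray:
        return np.array([o.abs_error for o in self.outcomes])


@dataclass(frozen=True)
class TFit:
    """Location-scale t fit; ``method`` flags fallbacks ('mle', 'mad',
    'degenerate')."""

    mu: float
    sigma: float
    df: float
    method: str = "mle"


@dataclass(frozen=True)
class BlockStats:
    block: int
    n: int
    mu: float
    sigma: float
    df: float
    success_rate: float
    corrected_sigma: float
    mean_abs_error: float
    is_partial: bool = False


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (deg) into (-180, 180]."""
    wrapped = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(wrapped) if np.isscalar(a) or np.ndim(a) == 0 else wrapped


def signed_directional_error(
    target_path: np.ndarray,
    start: Sequence[float],
    pocket_center: Sequence[float],
    min_displacement: float = 1e-6,
) -> float:
    """Signed angle (deg) from the desired start->pocket bearing to the target
    ball's initial movement bearing, wrapped to (-180, 180]."""
    path = np.asarray(target_path, dtype=float)
    start = np.asarray(start, dtype=float)
    disp = np.linalg.norm(path - start, axis=1)
    moved = np.nonzero(disp >= min_displacement)[0]
    if moved.size == 0:
        raise BallNotMovedError("target ball displacement below threshold")
    move_vec = path[moved[0]] - start
    desired = np.asarray(pocket_center, dtype=float) - start
    ang_move = math.degrees(math.atan2(move_vec[1], move_vec[0]))
    ang_des = math.degrees(math.atan2(desired[1], desired[0]))
    return float(wrap_angle(ang_move - ang_des))


def directional_error(
    target_path: np.ndarray,
    start: Sequence[float],
    pocket_center: Sequence[float],
    min_displacement: float = 1e-6,
) -> float:
    """Absolute angular difference (deg, in [0, 180]) between the target ball's
    initial movement direction and the direction to the pocket centre."""
    return abs(signed_directional_error(target_path, start, pocket_center, min_displacement))


def partition_blocks(
    outcomes: Sequence[ShotOutcome], block_size: int = DEFAULT_BLOCK_SIZE
) -> list[Block]:
    """Consecutive order-preserving blocks; a trailing partial block is kept
    and flagged. Concatenating the blocks reproduces the input."""
    if block_size <= 0:
        raise ConfigurationError("block_size must be positive")
    blocks = []
    for b, lo in enumerate(range(0, len(outcomes), block_size)):
        chunk = list(outcomes[lo : lo + block_size])
        blocks.append(Block(index=b, outcomes=chunk, is_partial=len(chunk) < block_size))
    return blocks


def success_rate(block: Block | Sequence[ShotOutcome]) -> float:
    outcomes = block.outcomes if isinstance(block, Block) else list(block)
    if not outcomes:
        raise UndefinedMetricError("success rate undefined for an empty block")
    return sum(o.success for o in outcomes) / len(outcomes)


def fit_block_t(errors: Sequence[float]) -> TFit:
    """Maximum-likelihood location-scale t fit of a block of values.

    n < 5 falls back to median / scaled-MAD (flagged); zero spread returns
    sigma 0 with df at the upper bound. The df estimate is clipped to
    [DF_MIN, DF_MAX] by a constrained refit for numerical stability.
    """
    x = np.asarray(errors, dtype=float)
    if x.size == 0:
        raise UndefinedMetricError("cannot fit an empty block")
    if np.ptp(x) == 0.0:
        return TFit(mu=float(x[0]), sigma=0.0, df=DF_MAX, method="degenerate")
    if x.size < 5:
        mad = np.median(np.abs(x - np.median(x)))
        return TFit(
            mu=float(np.median(x)), sigma=float(_MAD_TO_SD * mad), df=DF_MAX, method="mad"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df, loc, scale = stats.t.fit(x)
        if not (DF_MIN <= df <= DF_MAX) or not np.isfinite(df):
            df = float(np.clip(df if np.isfinite(df) else DF_MAX, DF_MIN, DF_MAX))
            df, loc, scale = stats.t.fit(x, fdf=df)
    return TFit(mu=float(loc), sigma=float(scale), df=float(df), method="mle")


def corrected_itv(directions: Sequence[float]) -> float:
    """t-fit scale of the residuals from an OLS line of direction vs
    within-block trial index (removes within-block learning trend)."""
    y = np.asarray(directions, dtype=float)
    if y.size < 2:
        raise UndefinedMetricError("need >= 2 trials for the trend regression")
    t = np.arange(y.size, dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    residuals = y - (slope * t + intercept)
    # rescale for the 2 fitted parameters so the scale estimate is not shrunk
    if y.size > 2:
        residuals = residuals * np.sqrt(y.size / (y.size - 2))
    return fit_block_t(residuals).sigma


def block_statistics(
    outcomes: Sequence[ShotOutcome], block_size: int = DEFAULT_BLOCK_SIZE
) -> list[BlockStats]:
    """Per-block robust statistics for one subject's session.

    (mu, sigma, df) are the t fit of the signed directions (sigma = ITV);
    ``mean_abs_error`` is the t-fit location of the absolute errors and
    carries the learning curve.
    """
    stats_out = []
    for block in partition_blocks(outcomes, block_size):
        tfit = fit_block_t(block.directions)
        err_fit = fit_block_t(block.abs_errors)
        stats_out.append(
            BlockStats(
                block=block.index,
                n=block.n,
                mu=tfit.mu,
                sigma=tfit.sigma,
                df=tfit.df,
                success_rate=success_rate(block),
                corrected_sigma=corrected_itv(block.directions),
                mean_abs_error=err_fit.mu,
                is_partial=block.is_partial,
            )
        )
    return stats_out
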