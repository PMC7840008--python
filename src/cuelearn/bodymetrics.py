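"""Full-body movement metrics per trial: covariance of joint-velocity
profiles, generalized variance, PC spectrum, DoF count, manipulative
complexity, and Velocity Profile Error (VPE) with its block variability."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import InsufficientDataError, UndefinedMetricError
from .performance import fit_block_t

DOF_THRESHOLD = 0.01  # PC variance fraction counted toward DoF
_SYMMETRY_TOL = 1e-8
_GV_CLIP_TOL = 1e-12

ComplexityMethod = Literal["participation_ratio", "entropy"]


@dataclass(frozen=True)
class PCSpectrum:
    """Normalized PC variance fractions, non-increasing, summing to 1."""

    variance_fractions: np.ndarray

    def __post_init__(self) -> None:
        fr = np.asarray(self.variance_fractions, dtype=float)
        if np.any(fr < -1e-12):
            raise UndefinedMetricError("variance fractions must be >= 0")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise UndefinedMetricError("variance fractions must sum to 1")
        object.__setattr__(self, "variance_fractions", np.maximum(fr, 0.0))

    def __len__(self) -> int:
        return self.variance_fractions.size


@dataclass(frozen=True)
class BodyMetrics:
    trial: int
    gv: float
    dof_count: int
    complexity: float
    vpe: np.ndarray  # per-channel, NaN where undefined


def trial_covariance(window: np.ndarray) -> np.ndarray:
    """Unbiased (n-1) sample covariance between channels over time samples."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise InsufficientDataError("need a (samples >= 2, channels) window")
    return np.cov(w, rowvar=False)


def generalized_variance(cov: np.ndarray) -> float:
    """Determinant of a symmetric covariance matrix, clipped at 0 when a
    numerically tiny negative value appears."""
    c = np.asarray(cov, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise UndefinedMetricError("covariance must be square")
    scale = max(np.abs(c).max(), 1.0)
    if np.abs(c - c.T).max() > _SYMMETRY_TOL * scale:
        raise UndefinedMetricError("covariance matrix is not symmetric")
    det = float(np.linalg.det(c))
    if det < 0 and det > -_GV_CLIP_TOL * scale ** c.shape[0]:
        det = 0.0
    return det


def pc_spectrum(window: np.ndarray) -> PCSpectrum:
    """Eigenvalues of the channel covariance, normalized to fractions and
    sorted descending (PCA across joints of one trial's velocity window)."""
    cov = trial_covariance(window)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.maximum(eig, 0.0)
    total = eig.sum()
    if total <= 0.0:
        raise UndefinedMetricError("zero total variance; spectrum undefined")
    return PCSpectrum(variance_fractions=eig / total)


def dof_count(spectrum: PCSpectrum, threshold: float = DOF_THRESHOLD) -> int:
    """Number of PCs explaining strictly more than ``threshold`` of variance."""
    return int(np.sum(spectrum.variance_fractions > threshold))


def manipulative_complexity(
    spectrum: PCSpectrum, method: ComplexityMethod = "participation_ratio"
) -> float:
    """Evenness of the PC spectrum on a fixed 0-1 scale.

    C = 1 when all PCs contribute equally; C = 0 when a single PC explains all
    variability. Default is the normalized participation ratio
    C = (PR - 1)/(N - 1) with PR = 1/sum(fractions^2); the 'entropy' method is
    C = (exp(H) - 1)/(N - 1) with H the Shannon entropy of the fractions. Both
    satisfy the boundary conditions above.
    """
    fr = spectrum.variance_fractions
    n = fr.size
    if n < 2:
        raise UndefinedMetricError("complexity undefined for fewer than 2 PCs")
    if method == "participation_ratio":
        pr = 1.0 / np.sum(fr**2)
    elif method == "entropy":
        nz = fr[fr > 0]
        pr = float(np.exp(-np.sum(nz * np.log(nz))))
    else:
        raise ValueError(f"unknown complexity method: {method!r}")
    return float((pr - 1.0) / (n - 1.0))


def _zscore_columns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each column; returns (z, valid) where invalid columns have
    zero variance."""
    centered = mat - mat.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0)
    valid = sd > 0
    z = np.zeros_like(centered)
    z[:, valid] = centered[:, valid] / sd[None, valid]
    return z, valid


def velocity_profile_error(
    trial_profile: np.ndarray,
    success_library: Sequence[np.ndarray],
    exclude_index: int | None = None,
) -> np.ndarray:
    """Per-channel VPE: min over successful trials of (1 - Pearson r) between
    this trial's velocity profile and each successful trial's, per channel.

    ``exclude_index`` drops one library entry (self-comparison of a successful
    trial). Zero-variance channels yield NaN. Values lie in [0, 2].
    """
    library = [w for i, w in enumerate(success_library) if i != exclude_index]
    if not library:
        raise UndefinedMetricError("success library empty after exclusion")
    trial = np.asarray(trial_profile, dtype=float)
    t_samples, n_channels = trial.shape
    zt, t_valid = _zscore_columns(trial)
    best = np.full(n_channels, np.inf)
    for lib in library:
        lib = np.asarray(lib, dtype=float)
        if lib.shape != trial.shape:
            raise UndefinedMetricError("library window shape mismatch")
        zl, l_valid = _zscore_columns(lib)
        r = np.einsum("tc,tc->c", zt, zl) / t_samples
        dist = 1.0 - r
        dist[~(t_valid & l_valid)] = np.inf
        best = np.minimum(best, dist)
    best[~t_valid] = np.nan
    best[np.isinf(best)] = np.nan
    return np.clip(best, 0.0, 2.0)  # NaN propagates through clip


def session_vpe(
    windows: Sequence[np.ndarray],
    success_flags: Sequence[bool],
    exclude_self: bool = True,
) -> np.ndarray:
    """VPE matrix (n_trials, n_channels) for a whole session.

    The success library pools all successful trials of the session; with
    ``exclude_self`` a successful trial is never compared to itself.
    """
    success_idx = [i for i, s in enumerate(success_flags) if s]
    if not success_idx:
        raise UndefinedMetricError("no successful trials in session")
    lib = [windows[i] for i in success_idx]
    out = []
    for i, win in enumerate(windows):
        excl = success_idx.index(i) if (exclude_self and i in success_idx) else None
        if excl is not None and len(lib) == 1:
            out.append(np.full(win.shape[1], np.nan))
            continue
        out.append(velocity_profile_error(win, lib, exclude_index=excl))
    return np.vstack(out)


def vpe_block_variability(vpes: np.ndarray) -> np.ndarray:
    """Per-channel robust scale (t-fit sigma) of VPEs within one block.

    ``vpes`` is (n_trials_in_block, n_channels); channels with any undefined
    VPE get NaN scale.
    """
    vpes = np.asarray(vpes, dtype=float)
    if vpes.shape[0] < 5:
        raise InsufficientDataError("need >= 5 trials in block")
    scales = np.empty(vpes.shape[1])
    for c in range(vpes.shape[1]):
        col = vpes[:, c]
        if np.any(np.isnan(col)):
            scales[c] = np.nan
        else:
            scales[c] = fit_block_t(col).sigma
    return scales


def trial_body_metrics(
    trial: int,
    window: np.ndarray,
    vpe: np.ndarray,
    complexity_method: ComplexityMethod = "participation_ratio",
) -> BodyMetrics:
    spectrum = pc_spectrum(window)
    return BodyMetrics(
        trial=trial,
        gv=generalized_variance(trial_covariance(window)),
        dof_count=dof_count(spectrum),
        complexity=manipulative_complexity(spectrum, complexity_method),
        vpe=vpe,
    )
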