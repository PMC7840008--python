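"""Learning-curve fits (exponential / double-exponential over trials) and the
first-to-last-block learning delta with its paired t-test."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InsufficientDataError, UndefinedMetricError

#: Multi-start grid of time constants (trials), fixed to avoid local minima.
TAU_GRID: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0)


@dataclass
class LearningCurveFit:
    model: str  # "exponential" | "double_exponential"
    params: dict[str, float]
    rss: float
    converged: bool
    diagnostics: str = ""

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "exponential":
            return p["c"] + p["a"] * np.exp(-t / p["tau"])
        return (
            p["c"]
            + p["a1"] * np.exp(-t / p["tau1"])
            - p["a2"] * np.exp(-t / p["tau2"])
        )


def _rss(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sum((y - yhat) ** 2))


def _linear_exp_fit(t: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float, float]:
    """For fixed tau, least-squares (c, a) of y = c + a exp(-t/tau)."""
    basis = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_exponential(series: Sequence[float]) -> LearningCurveFit:
    """Least-squares fit of y(t) = c + a exp(-t/tau), t = 0..n-1.

    Multi-start over TAU_GRID (with (c, a) solved linearly per start); the
    best-RSS refined solution is returned.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 10:
        raise InsufficientDataError("need >= 10 points for the exponential fit")
    t = np.arange(y.size, dtype=float)

    def residuals(p):
        c, a, tau = p
        return c + a * np.exp(-t / tau) - y

    best = None
    for tau0 in TAU_GRID:
        c0, a0, _ = _linear_exp_fit(t, y, tau0)
        try:
            sol = optimize.least_squares(
                residuals,
                x0=[c0, a0, tau0],
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            )
        except Exception:
            continue
        rss = _rss(y, y + sol.fun)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return LearningCurveFit(
            model="exponential",
            params={"c": float(np.mean(y)), "a": 0.0, "tau": 1.0},
            rss=_rss(y, np.full_like(y, np.mean(y))),
            converged=False,
            diagnostics="all starts failed",
        )
    rss, sol = best
    c, a, tau = sol.x
    # never report a fit worse than the flat line
    flat_rss = _rss(y, np.full_like(y, np.mean(y)))
    if rss > flat_rss:
        return LearningCurveFit(
            model="exponential",
            params={"c": float(np.mean(y)), "a": 0.0, "tau": float(tau)},
            rss=flat_rss,
            converged=bool(sol.success),
        )
    return LearningCurveFit(
        model="exponential",
        params={"c": float(c), "a": float(a), "tau": float(tau)},
        rss=rss,
        converged=bool(sol.success),
    )


def fit_double_exponential(series: Sequence[float]) -> LearningCurveFit:
    """Least-squares fit of y(t) = c + a1 exp(-t/tau1) - a2 exp(-t/tau2)
    with tau2 < tau1 (fast-rise, slow-decay shape).

    The constraint is enforced by fitting (c, a1, a2, tau2, dtau > 0) with
    tau1 = tau2 + dtau. Starts: all ordered TAU_GRID pairs plus the best
    single-exponential solution (a2 = 0), which guarantees the nested-model
    RSS bound.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 20:
        raise InsufficientDataError("need >= 20 points for the double-exponential fit")
    t = np.arange(y.size, dtype=float)

    def unpack(p):
        c, a1, a2, tau2, dtau = p
        return c, a1, a2, tau2 + dtau, tau2

    def residuals(p):
        c, a1, a2, tau1, tau2 = unpack(p)
        return c + a1 * np.exp(-t / tau1) - a2 * np.exp(-t / tau2) - y

    single = fit_exponential(series)
    starts = [
        [
            single.params["c"],
            single.params["a"],
            0.0,
            max(single.params["tau"] / 2.0, 1e-3),
            max(single.params["tau"] / 2.0, 1e-3),
        ]
    ]
    for tau2 in TAU_GRID:
        for tau1 in TAU_GRID:
            if tau1 <= tau2:
                continue
            c0, a10, _ = _linear_exp_fit(t, y, tau1)
            starts.append([c0, a10, abs(a10), tau2, tau1 - tau2])
    lb = [-np.inf, -np.inf, -np.inf, 1e-6, 1e-9]
    ub = [np.inf, np.inf, np.inf, np.inf, np.inf]
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(residuals, x0=x0, bounds=(lb, ub))
        except Exception:
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return LearningCurveFit(
            model="double_exponential",
            params={
                "c": single.params["c"],
                "a1": single.params["a"],
                "a2": 0.0,
                "tau1": single.params["tau"],
                "tau2": single.params["tau"] / 2.0,
            },
            rss=single.rss,
            converged=False,
            diagnostics="all starts failed; single-exponential fallback",
        )
    rss, sol = best
    # nested-model guarantee: never worse than the single-exponential fit
    if rss > single.rss:
        return LearningCurveFit(
            model="double_exponential",
            params={
                "c": single.params["c"],
                "a1": single.params["a"],
                "a2": 0.0,
                "tau1": single.params["tau"],
                "tau2": single.params["tau"] / 2.0,
            },
            rss=single.rss,
            converged=single.converged,
        )
    c, a1, a2, tau1, tau2 = unpack(sol.x)
    return LearningCurveFit(
        model="double_exponential",
        params={
            "c": float(c),
            "a1": float(a1),
            "a2": float(a2),
            "tau1": float(tau1),
            "tau2": float(tau2),
        },
        rss=rss,
        converged=bool(sol.success),
    )


@dataclass(frozen=True)
class LearningDelta:
    mean: float
    sd: float
    sem: float
    t: float
    p: float
    n: int
    p_defined: bool = True


def learning_delta(
    per_subject_block_means: np.ndarray,
    first_block: int = 0,
    last_block: int = -1,
) -> LearningDelta:
    """Per-subject (first - last) block-mean difference with a two-sided
    paired t-test across subjects.

    ``per_subject_block_means`` is (n_subjects, n_blocks). Zero variance of
    the differences leaves p undefined (flagged).
    """
    m = np.asarray(per_subject_block_means, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise InsufficientDataError("need >= 2 subjects with block means")
    diffs = m[:, first_block] - m[:, last_block]
    n = diffs.size
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    sem = sd / np.sqrt(n)
    if sd == 0.0:
        return LearningDelta(mean=mean, sd=0.0, sem=0.0, t=np.nan, p=np.nan, n=n,
                             p_defined=False)
    res = stats.ttest_rel(m[:, first_block], m[:, last_block])
    return LearningDelta(
        mean=mean, sd=sd, sem=sem, t=float(res.statistic), p=float(res.pvalue), n=n
    )
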