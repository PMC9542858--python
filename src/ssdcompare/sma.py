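"""Standardized major axis (model II) line fitting.

Ordinary least squares is inappropriate when both variables carry
comparable error, as they do when each axis is an estimated SSD
parameter. The SMA line minimizes the summed triangular areas between
points and line; its slope is

    b = sign(r) · SD(y) / SD(x),    a = mean(y) − b · mean(x).

The analytic slope confidence interval follows the classical F-based
construction: with B = F(1−α; 1, n−2) · (1−r²)/(n−2) the bounds are
b·(√(B+1) ± √B). The intercept (elevation) interval uses a t interval
with

    SE(a)² = Var(y − b·x)/n + mean(x)² · Var(b),
    Var(b) = b² · (1−r²)/(n−2).

A case-resampling bootstrap is provided as an independent check on the
analytic intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


class DegenerateInputError(ValueError):
    """x or y has zero variance: no SMA line is identified."""


@dataclass
class SMAResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    alpha: float


def _validate(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"SMA needs n >= 3, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in x or y")


def sma_fit(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> SMAResult:
    """Fit the SMA line with analytic 100·(1−alpha)% confidence intervals.

    Perfectly collinear data (|r| = 1) are legal: both intervals
    collapse to the point estimates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    n = x.size
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    sign = 1.0 if r >= 0 else -1.0
    b = sign * sy / sx
    a = float(np.mean(y)) - b * float(np.mean(x))
    r2 = r * r

    big_b = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r2) / (n - 2)
    lo, hi = b * (np.sqrt(big_b + 1) - np.sqrt(big_b)), b * (np.sqrt(big_b + 1) + np.sqrt(big_b))
    slope_ci = (min(lo, hi), max(lo, hi))

    var_b = b * b * (1 - r2) / (n - 2)
    resid_var = float(np.var(y - b * x, ddof=1))
    se_a = np.sqrt(resid_var / n + float(np.mean(x)) ** 2 * var_b)
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    intercept_ci = (a - t * se_a, a + t * se_a)

    return SMAResult(slope=b, intercept=a, r_squared=r2,
                     slope_ci=slope_ci, intercept_ci=intercept_ci,
                     n=n, alpha=alpha)


def sma_bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile bootstrap intervals for the SMA slope and intercept.

    Cases (x_i, y_i) are resampled with replacement and the line refit;
    a resample with zero variance on either axis is redrawn (up to 100
    retries per replicate). Deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentiles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.size

    def refit(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xb, yb = x[idx], y[idx]
        mx, my = xb.mean(axis=1), yb.mean(axis=1)
        dx, dy = xb - mx[:, None], yb - my[:, None]
        vx, vy = (dx * dx).sum(axis=1), (dy * dy).sum(axis=1)
        cov = (dx * dy).sum(axis=1)
        degenerate = (vx == 0) | (vy == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(cov >= 0, 1.0, -1.0) * np.sqrt(vy / vx)
        return b, my - b * mx, degenerate

    idx = rng.integers(0, n, size=(n_boot, n))
    slopes, intercepts, degenerate = refit(idx)
    for _ in range(100):
        if not degenerate.any():
            break
        redo = np.flatnonzero(degenerate)
        b, a, still = refit(rng.integers(0, n, size=(redo.size, n)))
        slopes[redo], intercepts[redo] = b, a
        degenerate[redo] = still
    else:
        raise RuntimeError("could not draw a non-degenerate bootstrap resample")
    q = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    s_lo, s_hi = np.percentile(slopes, q)
    a_lo, a_hi = np.percentile(intercepts, q)
    return (float(s_lo), float(s_hi)), (float(a_lo), float(a_hi))
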