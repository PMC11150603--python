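"""Goodness-of-fit via the probability integral transform (PIT).

If the fitted conditional gamma model describes the data, then
``U_t = F(Y_t | Theta_t)`` is i.i.d. Uniform[0,1].  Departures are assessed
with the empirical CDF of the ``U_t`` against the diagonal, the one-sample
Kolmogorov-Smirnov statistic, and asymptotic 95% KS bands
(``+-1.358/sqrt(T)`` around the 45-degree line).  The bands are pointwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .glm import GammaGlmModel, fit

__all__ = [
    "PitSeries",
    "ProbabilityPlot",
    "conditional_cdf",
    "pit",
    "ecdf",
    "ks_statistic",
    "segment_pit",
]

KS_CRIT_95 = 1.3581  # two-sided asymptotic KS critical value at 95%


@dataclass
class PitSeries:
    """PIT values U_t in [0, 1]."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if np.any((self.u < 0) | (self.u > 1)):
            raise ValueError("PIT values must lie in [0, 1]")

    @property
    def T(self) -> int:
        return self.u.size

    @property
    def degenerate(self) -> bool:
        """All PIT values (numerically) identical — e.g. constant data."""
        return bool(np.ptp(self.u) < 1e-12)


@dataclass
class ProbabilityPlot:
    """ECDF of the PIT values with a 95% KS band around the diagonal."""

    grid_u: np.ndarray
    ecdf: np.ndarray
    band_95: tuple[np.ndarray, np.ndarray]


def conditional_cdf(y, theta, model: GammaGlmModel) -> np.ndarray:
    """Conditional gamma CDF F(y | theta) of the fitted model.

    The regularized lower incomplete gamma function at shape ``alpha`` and
    rate ``alpha * exp(-L(theta))``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("amplitudes must be non-negative")
    rate = model.rate(np.atleast_1d(theta))
    out = special.gammainc(model.alpha, rate * y)
    return out if np.ndim(y) else float(np.atleast_1d(out)[0])


def pit(y, theta, model: GammaGlmModel) -> PitSeries:
    """Probability integral transform of the data through the fitted model."""
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if y.size != theta.size:
        raise ValueError("y and theta must have equal length")
    series = PitSeries(conditional_cdf(y, theta, model))
    if series.degenerate:
        warnings.warn("degenerate PIT: all values identical", stacklevel=2)
    return series


def ecdf(u: PitSeries, grid=None) -> ProbabilityPlot:
    """Empirical CDF of the PIT values on a grid, with 95% KS band."""
    if u.T < 1:
        raise ValueError("need at least one PIT value")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    grid = np.asarray(grid, dtype=float)
    us = np.sort(u.u)
    F = np.searchsorted(us, grid, side="right") / u.T
    half = KS_CRIT_95 / np.sqrt(u.T)
    lower = np.clip(grid - half, 0.0, 1.0)
    upper = np.clip(grid + half, 0.0, 1.0)
    return ProbabilityPlot(grid_u=grid, ecdf=F, band_95=(lower, upper))


def ks_statistic(u: PitSeries) -> tuple[float, float]:
    """One-sample two-sided KS statistic of the PIT values vs Uniform[0,1]."""
    res = stats.kstest(u.u, "uniform")
    return float(res.statistic), float(res.pvalue)


def segment_pit(y, theta, fs: float, window_sec: float = 1.0,
                K: int = 2) -> list[PitSeries]:
    """Fit and PIT on consecutive non-overlapping windows of a long recording.

    Mirrors the per-segment assessment used for continuous recordings: each
    ``window_sec`` chunk gets its own gamma-GLM fit (fixed order ``K``) and
    its own PIT series.
    """
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = int(round(window_sec * fs))
    if n < 2 * (2 * K + 1):
        raise ValueError("window too short for the requested model order")
    out = []
    for start in range(0, y.size - n + 1, n):
        sl = slice(start, start + n)
        model = fit(y[sl], theta[sl], K)
        out.append(pit(y[sl], theta[sl], model))
    return out
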