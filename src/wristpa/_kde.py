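"""Kernel density estimation with diffusion-based bandwidth selection.

Gaussian KDE where the bandwidth solves the fixed-point equation of the
diffusion estimator: the smoothing time ``t`` satisfies
``t = xi * gamma^[l](t)`` expressed through successive plug-in estimates of
the squared density-derivative functionals, evaluated in the cosine
(DCT) domain of the binned data. This selector is far less prone to the
over-smoothing of rule-of-thumb bandwidths on multi-modal data, which is
exactly the regime of stratified activity-intensity distributions.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft
from scipy import optimize

from .core import DataError

__all__ = ["kde_diffusion"]

_MIN_VALUES = 30


def _fixed_point(t: float, n: int, k2: np.ndarray, a2: np.ndarray) -> float:
    """t minus the plug-in estimate of t; its root is the bandwidth time."""
    ell = 7
    f = 2.0 * np.pi ** (2 * ell) * np.sum(k2**ell * a2 * np.exp(-k2 * np.pi**2 * t))
    for s in range(ell - 1, 1, -1):
        if f <= 0:  # all spectral mass smoothed away at this t
            return t
        k0 = np.prod(np.arange(1, 2 * s, 2)) / np.sqrt(2 * np.pi)
        const = (1 + 0.5 ** (s + 0.5)) / 3.0
        time = (2 * const * k0 / (n * f)) ** (2.0 / (3 + 2 * s))
        f = 2.0 * np.pi ** (2 * s) * np.sum(k2**s * a2 * np.exp(-k2 * np.pi**2 * time))
    if f <= 0:  # all spectral mass smoothed away at this t
        return t
    return t - (2.0 * n * np.sqrt(np.pi) * f) ** (-0.4)


def kde_diffusion(
    values: np.ndarray,
    n_grid: int = 2**12,
    limits: tuple[float, float] | None = None,
):
    """Density of a 1-D sample on a regular grid.

    Returns ``(grid, density, bandwidth)``. The density is non-negative and
    integrates to one over the grid (trapezoidal rule) to well within 1e-3.

    Raises ``DataError`` for fewer than 30 finite values or a degenerate
    (constant) sample.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < _MIN_VALUES:
        raise DataError(
            f"density estimation needs at least {_MIN_VALUES} finite values, "
            f"got {len(values)}"
        )
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0:
        raise DataError("degenerate (constant) sample: density support is a point")
    if limits is None:
        pad = (hi - lo) / 10.0
        limits = (lo - pad, hi + pad)
    span = limits[1] - limits[0]

    hist, edges = np.histogram(values, bins=n_grid, range=limits)
    n_unique = len(np.unique(values))
    binned = hist / hist.sum()
    a = sp_fft.dct(binned, type=2, norm=None)
    # the k = 0 coefficient carries only total mass; the functional
    # estimates use k >= 1
    k2 = np.arange(1, n_grid, dtype=float) ** 2
    a2 = (a[1:] / 2.0) ** 2

    t_star = _solve_bandwidth_time(n_unique, k2, a2)
    smoothed = a * np.exp(-np.arange(n_grid) ** 2 * np.pi**2 * t_star / 2.0)
    density = sp_fft.idct(smoothed, type=2, norm=None) / (2.0 * span)
    density = np.maximum(density, 0.0)
    grid = (edges[:-1] + edges[1:]) / 2.0
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise DataError("density estimate degenerated to zero mass")
    density /= area
    bandwidth = np.sqrt(t_star) * span
    return grid, density, bandwidth


def _solve_bandwidth_time(n: int, k2: np.ndarray, a2: np.ndarray) -> float:
    """Root of the fixed-point equation, with a plug-in fallback."""
    ts = np.logspace(-10, 0, 60)
    vals = np.array([_fixed_point(t, n, k2, a2) for t in ts])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if len(sign_change):
        i = sign_change[0]
        return float(optimize.brentq(_fixed_point, ts[i], ts[i + 1], args=(n, k2, a2)))
    # no root bracketed (tiny or pathological samples): rule-of-thumb time
    return 0.28 * n ** (-0.4)
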