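"""Gaussian kernel density estimation with Scott's-rule bandwidth.

Each region's voxel-intensity sample is turned into a probability density
on a 1-D grid.  Pairs of regions are always compared on a common grid
built from their pooled samples so the divergence integral sees shared
support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: default number of evaluation points
GRID_POINTS = 256
#: densities are floored at this value before any logarithm
DENSITY_FLOOR = 1e-12
#: the grid must extend this many bandwidths beyond the sample range
GRID_PADDING_BANDWIDTHS = 3.0


@dataclass
class DensityEstimate:
    """A probability density function evaluated on a 1-D grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise ValueError("grid and density must be 1-D arrays of equal length")
        if not (np.diff(self.grid) > 0).all():
            raise ValueError("grid must be strictly increasing")
        if not np.isfinite(self.density).all() or (self.density < 0).any():
            raise ValueError("density must be finite and non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def scott_bandwidth(sample: np.ndarray) -> float:
    """Scott's-rule kernel bandwidth for 1-D data: ``sd * n**(-1/5)``.

    Uses the sample (n-1 denominator) standard deviation.  Raises for
    degenerate samples (n < 2 or zero variance) for which no meaningful
    density can be estimated.
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 observations for a bandwidth, got {n}")
    sd = float(np.std(x, ddof=1))
    # ptp check catches constant samples whose np.std is round-off noise
    if not np.isfinite(sd) or sd <= 0 or np.ptp(x) == 0:
        raise ValueError("sample has zero variance; density estimate is degenerate")
    return sd * n ** (-1.0 / 5.0)


def make_common_grid(
    samples: Sequence[np.ndarray],
    n_points: int = GRID_POINTS,
) -> np.ndarray:
    """Shared evaluation grid covering all samples plus 3-bandwidth tails.

    The span is ``[min(pooled) - 3*h_max, max(pooled) + 3*h_max]`` where
    ``h_max`` is the largest Scott bandwidth among the samples.
    """
    if not samples:
        raise ValueError("need at least one sample")
    arrays = [np.asarray(s, dtype=float).ravel() for s in samples]
    h_max = max(scott_bandwidth(a) for a in arrays)
    lo = min(float(a.min()) for a in arrays) - GRID_PADDING_BANDWIDTHS * h_max
    hi = max(float(a.max()) for a in arrays) + GRID_PADDING_BANDWIDTHS * h_max
    return np.linspace(lo, hi, n_points)


def estimate_pdf(
    sample: np.ndarray,
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    floor: float = DENSITY_FLOOR,
) -> DensityEstimate:
    """Gaussian KDE of ``sample`` evaluated on ``grid``.

    The raw estimate ``(1/(n h)) * sum_i K((x - v_i)/h)`` is renormalized
    so its trapezoid integral over the grid is 1, then floored at
    ``floor`` (so downstream logarithms never see 0) and renormalized
    again.  The grid must cover the sample range padded by 3 bandwidths,
    otherwise probability mass would be silently truncated.
    """
    x = np.asarray(sample, dtype=float).ravel()
    h = scott_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = make_common_grid([x])
    grid = np.asarray(grid, dtype=float)
    pad = GRID_PADDING_BANDWIDTHS * h
    span = grid[-1] - grid[0]
    tol = 1e-9 * max(span, 1.0)
    if grid[0] > x.min() - pad + tol or grid[-1] < x.max() + pad - tol:
        raise ValueError(
            "grid does not cover sample range +/- 3 bandwidths; mass would be truncated"
        )
    z = (grid[np.newaxis, :] - x[:, np.newaxis]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=0) / (x.size * h * np.sqrt(2.0 * np.pi))
    dens /= np.trapezoid(dens, grid)
    dens = np.maximum(dens, floor)
    dens /= np.trapezoid(dens, grid)
    dens = np.maximum(dens, floor)
    return DensityEstimate(grid=grid, density=dens, bandwidth=h, n=x.size)
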