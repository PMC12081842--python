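"""Convert event populations into quantized density images.

Each plot's events are binned onto the plot's pixel grid (a pixel bin map
per dimension), sparse plots are optionally up-sampled by mass-preserving
Gaussian smoothing, and bin counts are normalized into a small number of
gray levels with a logarithmic law so that dense and sparse regions both
contribute usable image structure for registration.

Conventions: bins are half-open [i/W, (i+1)/W) with the final bin closed at
the top edge, so a value of exactly 1.0 lands in the last bin; row 0 of a
2-D grid corresponds to plot value y = 0 (origin bottom-left — renderers
flip vertically for display).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .model import EventTable, PlotSpec

logger = logging.getLogger(__name__)

__all__ = [
    "CountGrid",
    "DensityImage",
    "UpsampleConfig",
    "bin_events",
    "bin_histogram",
    "upsample_if_sparse",
    "counts_to_gray",
]


@dataclass
class CountGrid:
    """Raw per-pixel event counts for one plot (H x W, or length-W for 1-D)."""

    counts: np.ndarray
    plot: PlotSpec
    n_binned: int
    upsampled: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        expect = (
            (self.plot.image_width,)
            if self.plot.is_1d
            else (self.plot.image_height, self.plot.image_width)
        )
        if self.counts.shape != expect:
            raise ValueError(f"counts shape {self.counts.shape} != plot {expect}")


@dataclass
class DensityImage:
    """Quantized grayscale rendering of a CountGrid."""

    gray: np.ndarray  # integers in [0, gray_levels - 1], dtype uint8 for L <= 256
    plot: PlotSpec
    density_level: int
    gray_levels: int
    upsampled: bool = False

    def as_float(self) -> np.ndarray:
        """Lift to real values in [0, 1] for registration."""
        return self.gray.astype(float) / (self.gray_levels - 1)


@dataclass
class UpsampleConfig:
    """Sparseness heuristic controlling automatic up-sampling.

    A plot is considered sparse when fewer than ``sparse_frac`` of its bins
    are occupied or fewer than ``min_events`` events were binned; sparse
    grids are replaced by a Gaussian-smoothed copy (sigma in pixels) whose
    integer counts preserve total mass exactly via largest-remainder
    apportionment.
    """

    sparse_frac: float = 0.005
    min_events: int = 2000
    sigma: float = 1.5


def _bin_indices(v: np.ndarray, n: int) -> np.ndarray:
    idx = np.floor(v * n).astype(np.int64)
    return np.minimum(idx, n - 1)  # exact top edge closes into the last bin


def bin_events(events: EventTable, plot: PlotSpec) -> CountGrid:
    """Bin a (sub)population's events onto the 2-D pixel grid of a plot."""
    if plot.is_1d:
        return bin_histogram(events, plot)
    W, H = plot.image_width, plot.image_height
    x = events.column(plot.x_param)
    y = events.column(plot.y_param)
    ok = (x >= 0.0) & (x <= 1.0) & (y >= 0.0) & (y <= 1.0)
    ix = _bin_indices(x[ok], W)
    iy = _bin_indices(y[ok], H)
    flat = np.bincount(iy * W + ix, minlength=H * W)
    return CountGrid(flat.reshape(H, W), plot, int(ok.sum()))


def bin_histogram(events: EventTable, plot: PlotSpec) -> CountGrid:
    """1-D variant: histogram of the x parameter."""
    if not plot.is_1d:
        raise ValueError("bin_histogram requires a 1-D plot (y_param None)")
    W = plot.image_width
    x = events.column(plot.x_param)
    ok = (x >= 0.0) & (x <= 1.0)
    counts = np.bincount(_bin_indices(x[ok], W), minlength=W)
    return CountGrid(counts, plot, int(ok.sum()))


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Integerize non-negative weights so they sum exactly to ``total``."""
    scaled = weights * (total / weights.sum())
    base = np.floor(scaled).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        frac = (scaled - base).ravel()
        take = np.argsort(-frac, kind="stable")[:short]
        flat = base.ravel()
        flat[take] += 1
        base = flat.reshape(base.shape)
    return base


def upsample_if_sparse(grid: CountGrid, config: UpsampleConfig | None = None) -> CountGrid:
    """Replace a sparse grid with a mass-preserving smoothed copy."""
    cfg = config or UpsampleConfig()
    counts = grid.counts
    if grid.n_binned == 0 or counts.sum() == 0:
        return grid
    frac_nonzero = np.count_nonzero(counts) / counts.size
    if frac_nonzero >= cfg.sparse_frac and grid.n_binned >= cfg.min_events:
        return grid
    smoother = gaussian_filter1d if counts.ndim == 1 else gaussian_filter
    smoothed = smoother(counts.astype(float), cfg.sigma, mode="constant")
    new = _apportion(smoothed, int(counts.sum()))
    logger.debug(
        "up-sampled sparse grid (%.4f%% bins occupied, %d events)",
        100 * frac_nonzero,
        grid.n_binned,
    )
    return CountGrid(new, grid.plot, grid.n_binned, upsampled=True)


def counts_to_gray(grid: CountGrid, density_level: int, gray_levels: int) -> DensityImage:
    """Normalize bin counts into ``gray_levels`` gray shades.

    The density level ``d`` is subtracted from every count (floored at 0),
    filtering out regions with at most ``d`` events per pixel; the
    remainder is compressed logarithmically and scaled so the densest bin
    maps to the brightest level:

        gray = round((L - 1) * log(1 + max(c - d, 0)) / log(1 + max'))

    ``d = 0`` keeps maximum sensitivity to sparse areas; larger ``d``
    flattens the plot by discarding sparse structure.
    """
    if density_level < 0:
        raise ValueError("density_level must be >= 0")
    if not 2 <= gray_levels <= 256:
        raise ValueError("gray_levels must be in [2, 256]")
    c = np.maximum(grid.counts.astype(np.int64) - density_level, 0)
    m = c.max() if c.size else 0
    if m == 0:
        gray = np.zeros_like(c, dtype=np.uint8)
    else:
        gray = np.rint((gray_levels - 1) * np.log1p(c) / np.log1p(m)).astype(np.uint8)
    return DensityImage(
        gray=gray,
        plot=grid.plot,
        density_level=density_level,
        gray_levels=gray_levels,
        upsampled=grid.upsampled,
    )
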