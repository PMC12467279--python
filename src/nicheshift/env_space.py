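"""The 2-D environmental space (PCA-env) and kernel-density occupancy grids.

The niche-overlap framework works in a common environmental space: a PCA is
calibrated on the pooled environmental background of both ranges (the
"PCA-env" convention), occurrences and backgrounds are projected onto the
first two axes, and smoothed densities are evaluated on a shared R x R grid.
The occupancy surface ``z_cor`` divides occurrence density by background
density, so overlap reflects preference rather than mere climate
availability.

Density surfaces are binned kernel estimates: scores are histogrammed onto
the grid and convolved with a Gaussian kernel whose per-axis bandwidth
follows Silverman's rule.  The kernel is truncated at 4 bandwidths, which
both bounds the cost at O(R^2) and yields a finite occupied support (an
untruncated Gaussian kernel is nowhere exactly zero, which would make
expansion and unfilling degenerate downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA

from .climate import EnvMatrix

__all__ = ["EnvSpace", "DensityGrid", "fit_env_space", "project", "density_grid"]

#: Fractional margin added around the pooled background scores on each axis.
AXIS_MARGIN = 0.05

#: Kernel support truncation, in bandwidths.
KERNEL_TRUNCATE = 4.0


@dataclass
class EnvSpace:
    """A PCA basis fitted on the pooled background of both ranges.

    ``loadings`` columns are orthonormal directions in the standardized
    variable space (all axes kept for reporting; projections use the first
    two).  ``axis_ranges`` spans the pooled background scores on the first
    two axes with a 5% margin, defining the common density grid.
    """

    variables: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_variables, n_axes)
    explained: np.ndarray  # per-axis variance proportions, sums to 1
    axis_ranges: tuple[tuple[float, float], tuple[float, float]]


@dataclass
class DensityGrid:
    """Background, occurrence and occupancy densities on a shared R x R grid.

    All three surfaces are nonnegative and sum to 1.  ``z_cor`` is zero
    wherever the background density ``z_env`` is zero, and ``occupied_mask``
    marks cells with occurrence density support after kernel truncation.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    z_env: np.ndarray  # (ny, nx), background density
    z_occ: np.ndarray  # occurrence density
    z_cor: np.ndarray  # occupancy: occurrence density / background prevalence
    occupied_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.y_centers), len(self.x_centers))
        for name in ("z_env", "z_occ", "z_cor"):
            z = getattr(self, name)
            if z.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            if np.any(z < 0) or not np.isclose(z.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must be a nonnegative density summing to 1")
        if np.any(self.z_cor[self.z_env == 0] != 0):
            raise ValueError("z_cor must vanish outside the background support")

    @property
    def R(self) -> int:
        return len(self.x_centers)

    @classmethod
    def from_occupancy(cls, z_cor: np.ndarray, z_env: np.ndarray | None = None,
                       x_centers: np.ndarray | None = None,
                       y_centers: np.ndarray | None = None) -> "DensityGrid":
        """Build a grid directly from an occupancy surface (tests, worked examples).

        ``z_env`` defaults to uniform over all cells; ``z_occ`` is set equal
        to the (normalized) occupancy.
        """
        z_cor = np.atleast_2d(np.asarray(z_cor, dtype=float))
        z_cor = z_cor / z_cor.sum()
        if z_env is None:
            z_env = np.full_like(z_cor, 1.0 / z_cor.size)
        else:
            z_env = np.atleast_2d(np.asarray(z_env, dtype=float))
            z_env = z_env / z_env.sum()
        ny, nx = z_cor.shape
        if x_centers is None:
            x_centers = np.arange(nx, dtype=float)
        if y_centers is None:
            y_centers = np.arange(ny, dtype=float)
        return cls(np.asarray(x_centers, float), np.asarray(y_centers, float),
                   z_env=z_env, z_occ=z_cor.copy(), z_cor=z_cor,
                   occupied_mask=z_cor > 0)

    def same_grid(self, other: "DensityGrid") -> bool:
        return (self.z_env.shape == other.z_env.shape
                and np.allclose(self.x_centers, other.x_centers)
                and np.allclose(self.y_centers, other.y_centers))


def fit_env_space(background_native: EnvMatrix, background_invasive: EnvMatrix) -> EnvSpace:
    """Fit the PCA-env basis on pooled, standardized background rows.

    Both backgrounds must share the same variable columns and contribute at
    least 3 rows each.  Centering and unit-variance scaling use the pooled
    rows; axis ranges come from the pooled scores on the first two axes.
    """
    if background_native.variables != background_invasive.variables:
        raise ValueError("backgrounds must share the same variable columns")
    x = np.vstack([
        background_native.data.to_numpy(dtype=float),
        background_invasive.data.to_numpy(dtype=float),
    ])
    if len(background_native.data) < 3 or len(background_invasive.data) < 3:
        raise ValueError("each background needs at least 3 rows")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    if np.any(scale == 0):
        dead = [v for v, s in zip(background_native.variables, scale) if s == 0]
        raise ValueError(f"constant variables have zero variance: {dead}")
    z = (x - center) / scale
    n_axes = min(z.shape)
    pca = PCA(n_components=n_axes, svd_solver="full")
    scores = pca.fit_transform(z)
    explained = pca.explained_variance_ratio_
    explained = explained / explained.sum()
    ranges = []
    for axis in range(2):
        lo, hi = float(scores[:, axis].min()), float(scores[:, axis].max())
        margin = AXIS_MARGIN * (hi - lo)
        ranges.append((lo - margin, hi + margin))
    return EnvSpace(
        variables=list(background_native.variables),
        center=center,
        scale=scale,
        loadings=pca.components_.T,
        explained=explained,
        axis_ranges=(ranges[0], ranges[1]),
    )


def project(space: EnvSpace, env: EnvMatrix) -> np.ndarray:
    """Scores of rows on the first two PCA-env axes, shape (n, 2)."""
    missing = [v for v in space.variables if v not in env.data.columns]
    if missing:
        raise KeyError(f"environment matrix lacks fitted variables: {missing}")
    x = env.data[space.variables].to_numpy(dtype=float)
    z = (x - space.center) / space.scale
    return z @ space.loadings[:, :2]


def _silverman_sigma_cells(scores: np.ndarray, cell_sizes: np.ndarray,
                           multiplier: float) -> np.ndarray:
    """Per-axis Silverman bandwidth (d=2: sigma_j * n^(-1/6)) in cell units."""
    n = len(scores)
    sd = scores.std(axis=0, ddof=1)
    if np.any(sd == 0) or n < 2:
        raise ValueError("degenerate scores: zero spread on an axis")
    h = sd * n ** (-1.0 / 6.0) * multiplier
    return h / cell_sizes


def _binned_kde(scores: np.ndarray, x_edges: np.ndarray, y_edges: np.ndarray,
                sigma_cells: np.ndarray) -> np.ndarray:
    """Histogram scores on the grid and smooth with a truncated Gaussian kernel.

    Points are clipped into the grid extent so no mass is lost.  Returns a
    (ny, nx) density summing to 1.
    """
    x = np.clip(scores[:, 0], x_edges[0], x_edges[-1])
    y = np.clip(scores[:, 1], y_edges[0], y_edges[-1])
    hist, _, _ = np.histogram2d(y, x, bins=[y_edges, x_edges])
    z = gaussian_filter(hist, sigma=(sigma_cells[1], sigma_cells[0]),
                        mode="constant", truncate=KERNEL_TRUNCATE)
    total = z.sum()
    if total == 0:
        raise ValueError("density surface is identically zero")
    return z / total


def _grid_axes(space_or_ranges, R: int):
    ranges = getattr(space_or_ranges, "axis_ranges", space_or_ranges)
    (x0, x1), (y0, y1) = ranges
    x_edges = np.linspace(x0, x1, R + 1)
    y_edges = np.linspace(y0, y1, R + 1)
    x_centers = 0.5 * (x_edges[:-1] + x_edges[1:])
    y_centers = 0.5 * (y_edges[:-1] + y_edges[1:])
    return x_edges, y_edges, x_centers, y_centers


def occupancy_from_surfaces(z_occ: np.ndarray, z_env: np.ndarray) -> np.ndarray:
    """Prevalence-corrected occupancy: z_occ / z_env on the background support.

    Zero where the background has no density; renormalized to sum 1.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        z_cor = np.where(z_env > 0, z_occ / np.where(z_env > 0, z_env, 1.0), 0.0)
    total = z_cor.sum()
    if total == 0:
        raise ValueError("occupancy surface is zero everywhere on the background support")
    return z_cor / total


def density_grid(
    space: EnvSpace,
    occ_scores: np.ndarray,
    bg_scores: np.ndarray | None = None,
    R: int = 100,
    bandwidth_multiplier: float = 1.0,
    bg_surface: np.ndarray | None = None,
) -> DensityGrid:
    """Kernel-density background, occurrence and occupancy surfaces.

    ``bg_surface`` may carry a precomputed background density on the same
    grid (the background does not change across permutation replicates, so
    callers re-evaluating many occurrence sets pass it to avoid recomputing
    the most expensive surface).
    """
    occ_scores = np.asarray(occ_scores, dtype=float)
    if len(occ_scores) < 5:
        raise ValueError("need at least 5 occurrence scores")
    x_edges, y_edges, x_centers, y_centers = _grid_axes(space, R)
    cell = np.array([x_edges[1] - x_edges[0], y_edges[1] - y_edges[0]])

    if bg_surface is None:
        if bg_scores is None:
            raise ValueError("provide either bg_scores or a precomputed bg_surface")
        bg_scores = np.asarray(bg_scores, dtype=float)
        if len(bg_scores) < 20:
            raise ValueError("need at least 20 background scores")
        z_env = _binned_kde(bg_scores, x_edges, y_edges,
                            _silverman_sigma_cells(bg_scores, cell, bandwidth_multiplier))
    else:
        if bg_surface.shape != (R, R):
            raise ValueError("bg_surface shape must match the grid")
        z_env = bg_surface

    z_occ = _binned_kde(occ_scores, x_edges, y_edges,
                        _silverman_sigma_cells(occ_scores, cell, bandwidth_multiplier))
    z_cor = occupancy_from_surfaces(z_occ, z_env)
    return DensityGrid(
        x_centers=x_centers, y_centers=y_centers,
        z_env=z_env, z_occ=z_occ, z_cor=z_cor,
        occupied_mask=z_occ > 0,
    )


def background_surface(space: EnvSpace, bg_scores: np.ndarray, R: int = 100,
                       bandwidth_multiplier: float = 1.0) -> np.ndarray:
    """Background density alone, for reuse across permutation replicates."""
    bg_scores = np.asarray(bg_scores, dtype=float)
    if len(bg_scores) < 20:
        raise ValueError("need at least 20 background scores")
    x_edges, y_edges, _, _ = _grid_axes(space, R)
    cell = np.array([x_edges[1] - x_edges[0], y_edges[1] - y_edges[0]])
    return _binned_kde(bg_scores, x_edges, y_edges,
                       _silverman_sigma_cells(bg_scores, cell, bandwidth_multiplier))
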