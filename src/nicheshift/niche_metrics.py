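"""Niche overlap (Schoener's D) and the COUE dynamics decomposition.

Schoener's D between two occupancy surfaces is 1 minus half their L1
distance, so 1 means identical niches and 0 disjoint ones.  The COUE scheme
decomposes a niche change between a native and an invaded range into
Centroid shift, Overlap, Unfilling and Expansion, evaluated on analogue
climates only — grid cells whose conditions are available in both ranges'
backgrounds — so that a niche cannot appear to "expand" into conditions the
native range simply never offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env_space import DensityGrid

__all__ = [
    "schoener_d",
    "overlap_category",
    "coue_indices",
    "centroid_shift",
    "NicheComparison",
    "OVERLAP_CATEGORIES",
]

#: Half-open overlap bins (the top bin includes 1.0) with the conventional labels.
OVERLAP_CATEGORIES = [
    (0.0, 0.2, "no or very limited overlap"),
    (0.2, 0.4, "low overlap"),
    (0.4, 0.6, "moderate overlap"),
    (0.6, 0.8, "high overlap"),
    (0.8, 1.0, "very high overlap"),
]


def _check_shared_grid(a: DensityGrid, b: DensityGrid) -> None:
    if not a.same_grid(b):
        raise ValueError("density grids do not share resolution and axis ranges")


def schoener_d(grid_a: DensityGrid, grid_b: DensityGrid, surface: str = "z_cor") -> float:
    """Schoener's D = 1 - 0.5 * sum |pA - pB| over the shared grid.

    ``surface`` selects the occupancy variant: prevalence-corrected
    (``z_cor``, default) or raw occurrence density (``z_occ``).
    Symmetric in its arguments; ranges over [0, 1].
    """
    _check_shared_grid(grid_a, grid_b)
    pa = getattr(grid_a, surface)
    pb = getattr(grid_b, surface)
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def overlap_category(d: float) -> str:
    """Map a D value to the conventional five-level overlap label."""
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"D must lie in [0, 1], got {d}")
    for lo, hi, label in OVERLAP_CATEGORIES:
        if lo <= d < hi:
            return label
    return OVERLAP_CATEGORIES[-1][2]  # d == 1.0


def _analogue_mask(native: DensityGrid, invasive: DensityGrid,
                   intersection_quantile: float) -> np.ndarray:
    """Cells climatically available in both backgrounds.

    With quantile q > 0, each background keeps cells whose density exceeds
    its own q-quantile of positive density values; q = 0 keeps every strictly
    positive cell.
    """
    masks = []
    for grid in (native, invasive):
        z = grid.z_env
        if intersection_quantile > 0:
            positive = z[z > 0]
            thr = float(np.quantile(positive, intersection_quantile))
            masks.append(z >= thr)
        else:
            masks.append(z > 0)
    return masks[0] & masks[1]


def coue_indices(native: DensityGrid, invasive: DensityGrid,
                 intersection_quantile: float = 0.0) -> tuple[float, float, float]:
    """Expansion, stability and unfilling on analogue climates.

    - E: share of the invasive occupancy (within the analogue mask) lying in
      cells where the native niche is absent;
    - S = 1 - E: share overlapping the native niche;
    - U: share of the native occupancy lying in cells where the invasive
      niche is absent.

    Niche presence/absence in a cell uses each grid's ``occupied_mask``
    (kernel support truncated at 4 bandwidths).
    """
    _check_shared_grid(native, invasive)
    if not (0.0 <= intersection_quantile < 1.0):
        raise ValueError("intersection_quantile must lie in [0, 1)")
    analogue = _analogue_mask(native, invasive, intersection_quantile)
    if not analogue.any():
        raise ValueError("no analogue climates: background supports do not intersect")

    inv_mass = invasive.z_cor[analogue].sum()
    nat_mass = native.z_cor[analogue].sum()
    if inv_mass == 0 or nat_mass == 0:
        raise ValueError("a niche has no occupancy mass within analogue climates")

    expansion = invasive.z_cor[analogue & ~native.occupied_mask].sum() / inv_mass
    stability = 1.0 - expansion
    unfilling = native.z_cor[analogue & ~invasive.occupied_mask].sum() / nat_mass
    return float(expansion), float(stability), float(unfilling)


def _weighted_centroid(z: np.ndarray, x_centers: np.ndarray, y_centers: np.ndarray) -> np.ndarray:
    total = z.sum()
    if total == 0:
        raise ValueError("zero total density: centroid undefined")
    cx = float((z.sum(axis=0) * x_centers).sum() / total)
    cy = float((z.sum(axis=1) * y_centers).sum() / total)
    return np.array([cx, cy])


def centroid_shift(native: DensityGrid, invasive: DensityGrid) -> tuple[np.ndarray, np.ndarray]:
    """Centroid shifts (invasive minus native) in PC-score units.

    Returns the occurrence-density shift (occupancy surfaces) and the
    background shift (available environments); the latter separates a true
    niche shift from a mere change in what climates each range offers.
    """
    _check_shared_grid(native, invasive)
    occ_shift = (_weighted_centroid(invasive.z_cor, invasive.x_centers, invasive.y_centers)
                 - _weighted_centroid(native.z_cor, native.x_centers, native.y_centers))
    env_shift = (_weighted_centroid(invasive.z_env, invasive.x_centers, invasive.y_centers)
                 - _weighted_centroid(native.z_env, native.x_centers, native.y_centers))
    return occ_shift, env_shift


@dataclass
class NicheComparison:
    """One native-vs-invasive comparison: D, its category, COUE indices and shifts."""

    D: float
    category: str
    expansion: float
    stability: float
    unfilling: float
    centroid_occ_shift: tuple[float, float]
    centroid_env_shift: tuple[float, float]
    intersection_quantile: float = 0.0

    @classmethod
    def from_grids(cls, native: DensityGrid, invasive: DensityGrid,
                   intersection_quantile: float = 0.0) -> "NicheComparison":
        d = schoener_d(native, invasive)
        e, s, u = coue_indices(native, invasive, intersection_quantile)
        occ_shift, env_shift = centroid_shift(native, invasive)
        return cls(D=d, category=overlap_category(d), expansion=e, stability=s,
                   unfilling=u, centroid_occ_shift=tuple(occ_shift),
                   centroid_env_shift=tuple(env_shift),
                   intersection_quantile=intersection_quantile)

    def to_dict(self) -> dict:
        return {
            "schoener_d": self.D,
            "category": self.category,
            "expansion": self.expansion,
            "stability": self.stability,
            "unfilling": self.unfilling,
            "centroid_occ_shift": list(self.centroid_occ_shift),
            "centroid_env_shift": list(self.centroid_env_shift),
            "intersection_quantile": self.intersection_quantile,
        }

    def to_csv_row(self) -> dict:
        """One row in the conventional table column order."""
        return {
            "schoener_d": self.D,
            "expansion": self.expansion,
            "stability": self.stability,
            "unfilling": self.unfilling,
        }
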