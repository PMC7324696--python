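"""Cumulative dose-volume histograms and the rectal V55Gy endpoints.

The dependent quantities of the predictive models are DVH points on the
rectum: Pre-RV55, the percent of rectal volume receiving >= 55 Gy on the
pre-spacer plan, and dRV55, its reduction from the pre- to the post-spacer
plan. 55 Gy is the hypofractionated (60 Gy / 20 fx) analogue of the
conventional V70Gy toxicity threshold via the linear-quadratic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .geometry import ContourStack, slice_geometry

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "DoseMetrics",
    "DoseGridError",
    "compute_dvh",
    "v_at_dose",
    "paired_metrics",
    "structure_occupancy",
]


class DoseGridError(ValueError):
    """Structure/grid mismatch or malformed dose grid."""


@dataclass(frozen=True)
class DoseGrid:
    """Regular 3D scalar dose field in Gy.

    values has shape (nz, ny, nx); origin is the center of voxel
    (0, 0, 0) in mm (x, y, z); spacing is (dx, dy, dz) in mm.
    """

    origin: tuple
    spacing: tuple
    values: np.ndarray

    def __init__(self, origin, spacing, values):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise DoseGridError("dose values must be a 3D array (nz, ny, nx)")
        if np.any(values < 0):
            raise DoseGridError("dose values must be >= 0")
        origin = tuple(float(v) for v in origin)
        spacing = tuple(float(v) for v in spacing)
        if len(origin) != 3 or len(spacing) != 3:
            raise DoseGridError("origin and spacing must be (x, y, z) triples")
        if any(s <= 0 for s in spacing):
            raise DoseGridError("spacing must be positive")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "values", values)

    @property
    def dims(self) -> tuple:
        nz, ny, nx = self.values.shape
        return (nx, ny, nz)

    def z_positions(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.values.shape[0]) * self.spacing[2]


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: percent of structure volume at or above each dose edge."""

    dose_edges: np.ndarray
    relative_volume: np.ndarray

    def v_at(self, threshold_gy: float) -> float:
        return v_at_dose(self, threshold_gy)


@dataclass(frozen=True)
class DoseMetrics:
    """Paired pre/post-spacer rectal endpoints, all in percent."""

    pre_rv55: float
    post_rv55: float

    @property
    def delta_rv55(self) -> float:
        return self.pre_rv55 - self.post_rv55


def structure_occupancy(
    dose: DoseGrid, s: ContourStack, supersample: int = 2
) -> np.ndarray:
    """Fractional voxel occupancy of a structure on the dose grid.

    Voxels are scored by testing an in-plane ``supersample x supersample``
    grid of sub-points against the slice polygons (fractional occupancy
    reduces raster bias for thin walls such as the rectal wall). Grid planes
    are matched to structure slices by nearest z within half a slice spacing.
    """
    if s.is_empty:
        raise DoseGridError(f"structure '{s.name}' is empty")
    nz, ny, nx = dose.values.shape
    dx, dy, dz = dose.spacing
    x0, y0, z0 = dose.origin
    (sxmin, symin, szmin), (sxmax, symax, szmax) = s.bounding_box()
    if (
        sxmin < x0 - dx / 2 or sxmax > x0 + (nx - 0.5) * dx
        or symin < y0 - dy / 2 or symax > y0 + (ny - 0.5) * dy
        or szmin < z0 - dz / 2 or szmax > z0 + (nz - 0.5) * dz
    ):
        raise DoseGridError(
            f"structure '{s.name}' extends outside the dose grid bounds"
        )

    k = max(1, int(supersample))
    off = (np.arange(k) + 0.5) / k - 0.5  # sub-voxel offsets in voxel units
    xs = x0 + np.arange(nx)[:, None] * dx + off[None, :] * dx
    ys = y0 + np.arange(ny)[:, None] * dy + off[None, :] * dy
    gx, gy = np.meshgrid(xs.ravel(), ys.ravel())  # (ny*k, nx*k)

    occ = np.zeros((nz, ny, nx), dtype=float)
    for iz, z in enumerate(dose.z_positions()):
        sl = s.slice_at(z, tol=s.slice_spacing / 2)
        if sl is None or not sl.polygons:
            continue
        geom = slice_geometry(sl.polygons)
        if geom.is_empty:
            continue
        shapely.prepare(geom)
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
        inside = inside.reshape(ny * k, nx * k).astype(float)
        occ[iz] = inside.reshape(ny, k, nx, k).mean(axis=(1, 3))
    if occ.sum() == 0:
        raise DoseGridError(f"structure '{s.name}' covers no voxel of the grid")
    return occ


def compute_dvh(
    dose: DoseGrid, s: ContourStack, bin_width: float = 0.05, supersample: int = 2
) -> DVHCurve:
    """Cumulative relative-volume DVH of a structure on a dose grid.

    The curve is left-closed ("volume receiving >= dose") and normalized to
    the structure's own voxelized volume, so it starts at 100 % at 0 Gy and
    ends at 0 % above the maximum structure dose.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    occ = structure_occupancy(dose, s, supersample=supersample)
    w = occ.ravel()
    d = dose.values.ravel()
    sel = w > 0
    w, d = w[sel], d[sel]
    dmax = float(d.max())
    n_bins = int(np.ceil(dmax / bin_width)) + 2
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(d, bins=edges, weights=w)
    # volume at or above each left edge
    above = np.concatenate([np.cumsum(hist[::-1])[::-1], [0.0]])
    rel = 100.0 * above / w.sum()
    return DVHCurve(dose_edges=edges, relative_volume=rel)


def v_at_dose(c: DVHCurve, threshold_gy: float) -> float:
    """Percent of structure volume receiving >= ``threshold_gy``.

    Linear interpolation between bin edges; 100 % at 0 Gy and 0 % above the
    maximum dose.
    """
    if threshold_gy < 0:
        raise ValueError("dose threshold must be >= 0")
    if threshold_gy >= c.dose_edges[-1]:
        return 0.0
    return float(np.interp(threshold_gy, c.dose_edges, c.relative_volume))


def paired_metrics(
    pre_dose: DoseGrid,
    post_dose: DoseGrid,
    pre_rectum: ContourStack,
    post_rectum: ContourStack,
    threshold_gy: float = 55.0,
    bin_width: float = 0.05,
) -> DoseMetrics:
    """Pre/post-spacer rectal V(threshold) endpoints from paired plans.

    Each plan's V55 is computed on that plan's own rectum contour (the
    rectum moves when the spacer is implanted); dRV55 = pre - post.
    """
    pre = v_at_dose(compute_dvh(pre_dose, pre_rectum, bin_width), threshold_gy)
    post = v_at_dose(compute_dvh(post_dose, post_rectum, bin_width), threshold_gy)
    return DoseMetrics(pre_rv55=pre, post_rv55=post)
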