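"""Contour-stack geometry: derived structures and geometric metrics.

Structures are represented the way radiotherapy structure sets store them:
per-slice closed planar polygons on a common axial z-grid, in patient (LPS)
millimetre coordinates (x = patient left, y = posterior, z = superior).
From the primary contours (rectum, CTV) this module derives the planning
structures used downstream:

* ``expand_margin`` -- CTV -> PTV by anisotropic margin expansion
  (7 mm in every direction except 5 mm posteriorly, by default),
* ``make_wall`` -- whole organ -> 3 mm inner wall shell (rectal wall, RW),
* ``height_limit`` -- wall truncated 17.5 mm beyond the PTV's
  superior/inferior extent (RW17.5),

and computes the geometric quantities that feed the predictive models:
volumes, boolean overlap volumes (rectum-in-PTV) and the slice-wise 2D
Hausdorff distance between the rectal wall and the CTV (RWtoCTV).

All lengths are millimetres internally; volumes are reported in cc and
Hausdorff distances in cm to match clinical convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "ContourSlice",
    "ContourStack",
    "MarginSpec",
    "StructureRecipeConfig",
    "InvalidStructureError",
    "expand_margin",
    "make_wall",
    "height_limit",
    "volume",
    "overlap_volume",
    "slice_hausdorff",
    "mean_slice_hausdorff",
    "slice_geometry",
    "geometry_to_polygons",
]

#: tolerance (mm) for matching slice z positions across stacks
Z_TOL = 1e-6


class InvalidStructureError(ValueError):
    """Raised when a contour stack or polygon violates its invariants."""


def _normalize_polygon(poly) -> np.ndarray:
    """Return an (N, 2) float array with implicit closure (no repeated last vertex)."""
    arr = np.asarray(poly, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidStructureError(f"polygon must be (N, 2), got shape {arr.shape}")
    if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if len(np.unique(arr.round(decimals=9), axis=0)) < 3:
        raise InvalidStructureError("polygon needs >= 3 distinct vertices")
    return arr


@dataclass(frozen=True)
class ContourSlice:
    """One axial slice: z position (mm) and its closed polygons (mm)."""

    z: float
    polygons: tuple  # tuple of (N, 2) float arrays, implicit closure

    def __init__(self, z: float, polygons: Iterable) -> None:
        object.__setattr__(self, "z", float(z))
        object.__setattr__(
            self, "polygons", tuple(_normalize_polygon(p) for p in polygons)
        )


@dataclass(frozen=True)
class ContourStack:
    """Named structure as per-slice closed polygons on a uniform z-grid.

    Invariants: z strictly increasing with uniform spacing (gaps are allowed
    as slices simply absent from the list); every polygon closed with at
    least three distinct vertices and non-self-intersecting.
    """

    name: str
    slices: tuple
    slice_spacing: float

    def __init__(self, name: str, slices: Iterable, slice_spacing: float) -> None:
        object.__setattr__(self, "name", str(name))
        norm = []
        for s in slices:
            if isinstance(s, ContourSlice):
                norm.append(s)
            else:
                z, polys = s
                norm.append(ContourSlice(z, polys))
        norm.sort(key=lambda s: s.z)
        object.__setattr__(self, "slices", tuple(norm))
        object.__setattr__(self, "slice_spacing", float(slice_spacing))
        self._validate()

    def _validate(self) -> None:
        if self.slice_spacing <= 0:
            raise InvalidStructureError("slice_spacing must be positive")
        zs = self.z_positions
        if len(zs) > 1:
            dz = np.diff(zs)
            if np.any(dz <= 0):
                raise InvalidStructureError("z positions must be strictly increasing")
            # uniform grid: every gap is an integer multiple of the spacing
            ratio = dz / self.slice_spacing
            if not np.allclose(ratio, np.round(ratio), atol=1e-6):
                raise InvalidStructureError(
                    f"slice gaps must be multiples of spacing {self.slice_spacing}"
                )
        for s in self.slices:
            for p in s.polygons:
                if not Polygon(p).is_valid:
                    raise InvalidStructureError(
                        f"self-intersecting polygon on slice z={s.z} of '{self.name}'"
                    )

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z for s in self.slices], dtype=float)

    @property
    def is_empty(self) -> bool:
        return not any(s.polygons for s in self.slices)

    def slice_at(self, z: float, tol: float | None = None) -> ContourSlice | None:
        """Slice whose z matches ``z`` within tolerance, or None."""
        tol = self.slice_spacing / 2 if tol is None else tol
        for s in self.slices:
            if abs(s.z - z) <= tol:
                return s
        return None

    def bounding_box(self):
        """((xmin, ymin, zmin), (xmax, ymax, zmax)) in mm over all polygons."""
        if self.is_empty:
            raise InvalidStructureError(f"structure '{self.name}' is empty")
        pts = np.vstack([p for s in self.slices for p in s.polygons])
        zs = self.z_positions
        return (
            (pts[:, 0].min(), pts[:, 1].min(), zs.min()),
            (pts[:, 0].max(), pts[:, 1].max(), zs.max()),
        )


@dataclass(frozen=True)
class MarginSpec:
    """Anisotropic expansion margins in mm (patient LPS directions)."""

    anterior: float = 7.0
    posterior: float = 5.0
    left: float = 7.0
    right: float = 7.0
    superior: float = 7.0
    inferior: float = 7.0

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"margin '{f}' must be >= 0, got {v}")


@dataclass(frozen=True)
class StructureRecipeConfig:
    """Parameters of the derived-structure recipes.

    wall_thickness: in-plane shell thickness of organ wall structures (mm).
    height_limit_extent: how far the truncated wall extends beyond the
        PTV's most superior/inferior slices (mm).
    raster_resolution: in-plane grid pitch used for morphological
        operations (mm); vector (shoelace) areas are used wherever possible.
    """

    wall_thickness: float = 3.0
    height_limit_extent: float = 17.5
    raster_resolution: float = 1.0

    def __post_init__(self):
        if self.wall_thickness < 0:
            raise ValueError("wall_thickness must be >= 0")
        if self.height_limit_extent < 0:
            raise ValueError("height_limit_extent must be >= 0")
        if self.raster_resolution <= 0:
            raise ValueError("raster_resolution must be > 0")


# ---------------------------------------------------------------------------
# shapely helpers

def slice_geometry(polygons: Sequence) -> shapely.Geometry:
    """Combine a slice's polygons into one shapely geometry (even-odd rule).

    Nested rings alternate between filled regions and holes, matching how
    structure sets store annular slices (e.g. wall structures) as separate
    closed contours.
    """
    geom = Polygon()
    for p in polygons:
        poly = Polygon(np.asarray(p, dtype=float))
        if not poly.is_valid:
            poly = poly.buffer(0)
        geom = geom.symmetric_difference(poly)
    return geom


def geometry_to_polygons(geom) -> list:
    """Flatten a shapely (Multi)Polygon into rings as (N, 2) arrays.

    Exterior and interior rings come out as separate closed contours so they
    round-trip through :func:`slice_geometry`'s even-odd rule.
    """
    out = []
    if geom.is_empty:
        return out
    parts = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    for part in parts:
        if part.is_empty or not isinstance(part, Polygon):
            continue
        out.append(np.asarray(part.exterior.coords[:-1], dtype=float))
        for ring in part.interiors:
            out.append(np.asarray(ring.coords[:-1], dtype=float))
    return [p for p in out if len(p) >= 3]


# ---------------------------------------------------------------------------
# rasterization helpers

def _rasterize_slice(polygons, origin_xy, shape_yx, resolution) -> np.ndarray:
    """Boolean in-plane mask sampled at pixel centers (even-odd membership)."""
    ny, nx = shape_yx
    geom = slice_geometry(polygons)
    if geom.is_empty:
        return np.zeros((ny, nx), dtype=bool)
    xs = origin_xy[0] + (np.arange(nx) + 0.5) * resolution
    ys = origin_xy[1] + (np.arange(ny) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(geom)
    return shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(ny, nx)


def _mask_slice_to_polygons(mask2d, origin_xy, resolution) -> list:
    """Subpixel contours of a boolean mask, back in mm coordinates."""
    padded = np.pad(mask2d.astype(float), 1)
    polys = []
    for c in measure.find_contours(padded, 0.5):
        # rows are y, cols are x; un-pad and map pixel-center indices to mm
        y = origin_xy[1] + (c[:, 0] - 1 + 0.5) * resolution
        x = origin_xy[0] + (c[:, 1] - 1 + 0.5) * resolution
        ring = np.column_stack([x, y])
        if len(ring) >= 4:
            polys.append(ring[:-1] if np.allclose(ring[0], ring[-1]) else ring)
    return [p for p in polys if len(p) >= 3 and abs(Polygon(p).area) > resolution**2]


# ---------------------------------------------------------------------------
# derived-structure operations

def expand_margin(
    ctv: ContourStack, m: MarginSpec | None = None,
    cfg: StructureRecipeConfig | None = None, name: str | None = None,
) -> ContourStack:
    """Expand a structure by anisotropic margins (CTV -> PTV).

    Implemented as 3D morphological dilation of a rasterized mask with a
    per-direction scaled ellipsoidal structuring element (the standard TPS
    margin tool behaviour), then re-contoured per slice. The posterior
    margin acts along +y, superior along +z (LPS axes).
    """
    m = MarginSpec() if m is None else m
    cfg = StructureRecipeConfig() if cfg is None else cfg
    if ctv.is_empty:
        raise InvalidStructureError("cannot expand an empty structure")

    res = cfg.raster_resolution
    dz = ctv.slice_spacing
    (xmin, ymin, zmin), (xmax, ymax, zmax) = ctv.bounding_box()
    pad = max(m.left, m.right, m.anterior, m.posterior) + 2 * res
    origin_xy = (xmin - pad, ymin - pad)
    nx = int(math.ceil((xmax - xmin + 2 * pad) / res))
    ny = int(math.ceil((ymax - ymin + 2 * pad) / res))

    n_sup = int(math.floor(m.superior / dz + 0.5))
    n_inf = int(math.floor(m.inferior / dz + 0.5))
    zs_in = ctv.z_positions
    z0 = zs_in.min() - n_inf * dz
    nz = int(round((zs_in.max() - zs_in.min()) / dz)) + 1 + n_inf + n_sup
    z_out = z0 + np.arange(nz) * dz

    mask = np.zeros((nz, ny, nx), dtype=bool)
    for s in ctv.slices:
        iz = int(round((s.z - z0) / dz))
        mask[iz] = _rasterize_slice(s.polygons, origin_xy, (ny, nx), res)

    # structuring element: offsets (dk, dy, dx) with the per-sign ellipsoid
    #   (dx/mx)^2 + (dy/my)^2 + (dz/mz)^2 <= 1
    rx = int(math.ceil(max(m.left, m.right) / res))
    ry = int(math.ceil(max(m.anterior, m.posterior) / res))
    se = np.zeros((n_inf + n_sup + 1, 2 * ry + 1, 2 * rx + 1), dtype=bool)
    for k in range(-n_inf, n_sup + 1):
        mz = m.superior if k > 0 else m.inferior
        if k == 0:
            scale = 1.0
        else:
            frac = min(abs(k) * dz / mz, 1.0) if mz > 0 else 1.0
            scale = math.sqrt(max(0.0, 1.0 - frac * frac))
        for j in range(-ry, ry + 1):
            my = (m.posterior if j > 0 else m.anterior) * scale
            # half-voxel inflation: treat SE voxels as cells, not points,
            # so the discrete dilation is unbiased rather than shrunk
            my = my + res / 2 if my > 0 else my
            for i in range(-rx, rx + 1):
                mx = (m.left if i > 0 else m.right) * scale
                mx = mx + res / 2 if mx > 0 else mx
                tx = (i * res / mx) ** 2 if mx > 0 else (0.0 if i == 0 else np.inf)
                ty = (j * res / my) ** 2 if my > 0 else (0.0 if j == 0 else np.inf)
                if tx + ty <= 1.0 + 1e-12:
                    se[k + n_inf, j + ry, i + rx] = True
    dilated = ndimage.binary_dilation(mask, structure=se, origin=0)

    slices = []
    for iz in range(nz):
        polys = _mask_slice_to_polygons(dilated[iz], origin_xy, res)
        if polys:
            slices.append(ContourSlice(z_out[iz], polys))
    return ContourStack(name or f"{ctv.name}+margin", slices, dz)


def make_wall(
    organ: ContourStack, cfg: StructureRecipeConfig | None = None,
    name: str | None = None,
) -> ContourStack:
    """Inner wall shell of a whole organ (e.g. rectum -> RW).

    The wall is the organ minus its 3D erosion by ``wall_thickness``,
    computed on the vector contours: the eroded region on a slice is the
    intersection of negative buffers of that slice and its neighbours
    within the wall thickness, each by sqrt(t^2 - dz^2) (a sampled
    ball-erosion of the stacked-slab solid, so organ end caps become wall
    as a spherical-shell closed form requires). Slices too thin to erode
    keep the whole slice as wall (logged).
    """
    cfg = StructureRecipeConfig() if cfg is None else cfg
    if organ.is_empty:
        raise InvalidStructureError("cannot make a wall from an empty structure")
    t = cfg.wall_thickness
    h = organ.slice_spacing
    kmax = int(math.floor(t / h + 1e-9))
    slices = []
    for s in organ.slices:
        if not s.polygons:
            continue
        geom = slice_geometry(s.polygons)
        if t == 0:
            inner = geom
        else:
            inner = geom.buffer(-t)
            for k in range(1, kmax + 1):
                if inner.is_empty:
                    break
                r = math.sqrt(max(t * t - (k * h) ** 2, 0.0))
                for nz in (s.z - k * h, s.z + k * h):
                    neighbor = organ.slice_at(nz, tol=h / 4)
                    if neighbor is None or not neighbor.polygons:
                        inner = Polygon()  # organ ends within t: cap is wall
                        break
                    inner = inner.intersection(
                        slice_geometry(neighbor.polygons).buffer(-r)
                    )
        if t > 0 and inner.is_empty and geom.buffer(-t).is_empty:
            logger.info(
                "wall: slice z=%.2f of '%s' thinner than 2 x %.1f mm; "
                "using whole slice", s.z, organ.name, t,
            )
        wall = geom.difference(inner)
        polys = geometry_to_polygons(wall)
        if polys:
            slices.append(ContourSlice(s.z, polys))
    return ContourStack(name or f"{organ.name}_wall", slices, organ.slice_spacing)


def height_limit(
    wall: ContourStack, ptv: ContourStack,
    cfg: StructureRecipeConfig | None = None, name: str | None = None,
) -> ContourStack:
    """Truncate a wall to the PTV z-extent plus ``height_limit_extent``.

    Keeps exactly the wall slices whose z lies within
    [ptv_min_z - extent, ptv_max_z + extent]; retained contours are
    unchanged, so the operation is idempotent.
    """
    cfg = StructureRecipeConfig() if cfg is None else cfg
    if ptv.is_empty or wall.is_empty:
        raise InvalidStructureError("height_limit requires non-empty structures")
    zs = ptv.z_positions
    lo = zs.min() - cfg.height_limit_extent
    hi = zs.max() + cfg.height_limit_extent
    kept = [s for s in wall.slices if lo - Z_TOL <= s.z <= hi + Z_TOL]
    if not kept:
        logger.warning(
            "height_limit: '%s' and '%s' have disjoint z-ranges; empty result",
            wall.name, ptv.name,
        )
    return ContourStack(name or f"{wall.name}_limited", kept, wall.slice_spacing)


# ---------------------------------------------------------------------------
# metrics

def volume(s: ContourStack) -> float:
    """Structure volume in cc: per-slice shoelace area x slice spacing.

    Nested contours follow the even-odd rule, so holes are subtracted.
    """
    total_mm3 = 0.0
    for sl in s.slices:
        if sl.polygons:
            total_mm3 += slice_geometry(sl.polygons).area * s.slice_spacing
    return total_mm3 / 1000.0


def overlap_volume(a: ContourStack, b: ContourStack) -> float:
    """Boolean intersection volume of two structures in cc.

    Slices of ``b`` are matched to ``a``'s z-grid by nearest z within half a
    slice spacing; disjoint structures give 0.
    """
    total_mm3 = 0.0
    tol = min(a.slice_spacing, b.slice_spacing) / 2
    for sa in a.slices:
        sb = b.slice_at(sa.z, tol=tol)
        if sb is None or not sa.polygons or not sb.polygons:
            continue
        inter = slice_geometry(sa.polygons).intersection(slice_geometry(sb.polygons))
        total_mm3 += inter.area * a.slice_spacing
    return total_mm3 / 1000.0


def _boundary_points(boundary, step: float) -> np.ndarray:
    """Points sampled along a (multi)linestring at spacing <= step mm."""
    dense = shapely.segmentize(boundary, step)
    return shapely.get_coordinates(dense)


def _curve_hausdorff_mm(ba, bb, step: float, directed: bool) -> float:
    pa = _boundary_points(ba, step)
    pb = _boundary_points(bb, step)
    d_ab = float(np.max(shapely.distance(shapely.points(pa), bb)))
    if directed:
        return d_ab
    d_ba = float(np.max(shapely.distance(shapely.points(pb), ba)))
    return max(d_ab, d_ba)


def slice_hausdorff(p, q, directed: bool = False, sample_step: float = 0.05) -> float:
    """2D Hausdorff distance between two contour curves, in cm.

    Symmetric by default (max over both directed distances); the distance is
    measured between the contour *curves*, not the filled regions. One side
    is sampled densely (``sample_step`` mm) while point-to-curve distances
    are exact point-to-segment, so the result is accurate to well under the
    sampling step.
    """
    rings = []
    for poly in (p, q):
        arr = _normalize_polygon(poly)
        ring = shapely.LinearRing(np.vstack([arr, arr[:1]]))
        if ring.length == 0 or abs(Polygon(arr).area) == 0:
            raise InvalidStructureError("degenerate polygon in slice_hausdorff")
        rings.append(ring)
    return _curve_hausdorff_mm(rings[0], rings[1], sample_step, directed) / 10.0


def mean_slice_hausdorff(
    rw17: ContourStack, ctv: ContourStack,
    directed: bool = False, sample_step: float = 0.1,
) -> float:
    """Mean over shared slices of the 2D Hausdorff distance, in cm (RWtoCTV).

    Only slices where *both* structures have at least one polygon enter the
    (unweighted) mean; slices with multiple polygons are merged and the
    union boundary is used.
    """
    if rw17.is_empty or ctv.is_empty:
        raise InvalidStructureError("mean_slice_hausdorff requires non-empty stacks")
    tol = min(rw17.slice_spacing, ctv.slice_spacing) / 2
    dists = []
    for sa in rw17.slices:
        sb = ctv.slice_at(sa.z, tol=tol)
        if sb is None or not sa.polygons or not sb.polygons:
            continue
        ga, gb = slice_geometry(sa.polygons), slice_geometry(sb.polygons)
        if ga.is_empty or gb.is_empty:
            continue
        dists.append(_curve_hausdorff_mm(ga.boundary, gb.boundary, sample_step, directed))
    if not dists:
        raise InvalidStructureError(
            f"'{rw17.name}' and '{ctv.name}' share no populated slices"
        )
    return float(np.mean(dists)) / 10.0
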