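"""Synthetic phantom anatomy, surrogate dose and calibrated cohort simulation.

Clinical structure sets and plans for spacer patients are not publicly
available, so this module generates stand-ins at the published cohort's
scale:

* ``make_phantom`` -- a pelvic phantom: ellipsoidal CTV (prostate plus
  proximal seminal vesicles), a tubular rectum posterior to it at a
  controlled minimum gap, and a bladder, as contour stacks on a shared
  axial grid.
* ``apply_spacer`` -- displaces the rectum posteriorly with a raised-cosine
  taper (maximal at mid-gland, as hydrogel spacers separate the organs) and
  fills the vacated space with a spacer structure.
* ``surrogate_dose`` -- prescription dose inside the PTV with a sigmoidal
  falloff in distance to the PTV surface. This is *not* a VMAT dose engine;
  it exists to give geometry-dependent rectal V55 with the correct monotone
  structure (larger rectum-PTV gap => lower V55).
* ``simulate_cohort`` -- cohorts of feature vectors whose marginals are
  calibrated to the published 21-patient summary statistics, with endpoints
  either drawn from the published linear models plus matched noise
  ("model" mode) or measured through the full geometric pipeline
  ("geometric" mode).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely import affinity

from . import geometry
from .dvh import DoseGrid, paired_metrics
from .features import ENDPOINT_COLUMNS, FEATURE_COLUMNS, extract_features
from .geometry import (
    ContourSlice,
    ContourStack,
    MarginSpec,
    StructureRecipeConfig,
    geometry_to_polygons,
    slice_geometry,
)

__all__ = [
    "PhantomParams",
    "SpacerParams",
    "CohortSimConfig",
    "make_phantom",
    "apply_spacer",
    "surrogate_dose",
    "simulate_cohort",
]

_CIRCLE_VERTICES = 72


def _ellipse(cx, cy, rx, ry, n=_CIRCLE_VERTICES) -> np.ndarray:
    th = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([cx + rx * np.cos(th), cy + ry * np.sin(th)])


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of the synthetic pelvis (mm, patient LPS axes).

    Defaults give a ~40 cc CTV and ~79 cc rectum, the cohort-mean scale of
    the published study population.
    """

    ctv_semi_axes: tuple = (22.5, 19.0, 22.5)   # (x, y, z) -> ~40 cc
    rectum_radius: float = 15.0                  # tube radius -> ~78 cc at 110 mm
    rectum_length: float = 110.0
    rectum_curvature: float = 4.0                # lateral bow amplitude (mm)
    gap: float = 2.0                             # min CTV-rectum distance (mm)
    bladder_radius: float = 35.0
    slice_spacing: float = 2.0
    seed: int = 0
    shape_jitter: float = 0.03                   # fractional radius irregularity

    def __post_init__(self):
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if min(self.ctv_semi_axes) <= 0 or self.rectum_radius <= 0:
            raise ValueError("all dimensions must be positive")
        if self.rectum_length <= 0 or self.slice_spacing <= 0:
            raise ValueError("all dimensions must be positive")


@dataclass(frozen=True)
class SpacerParams:
    """Posterior rectal displacement produced by the hydrogel.

    max_displacement acts at mid-gland and tapers to zero with a raised
    cosine over the CTV z-extent plus ``taper_extent`` on each side.
    """

    max_displacement: float = 10.0
    taper_extent: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")


def _min_slice_distance(a: ContourStack, b: ContourStack) -> float:
    """Minimum over shared slices of the 2D distance between structures (mm)."""
    tol = min(a.slice_spacing, b.slice_spacing) / 2
    best = math.inf
    for sa in a.slices:
        sb = b.slice_at(sa.z, tol=tol)
        if sb is None or not sa.polygons or not sb.polygons:
            continue
        ga, gb = slice_geometry(sa.polygons), slice_geometry(sb.polygons)
        d = ga.distance(gb)
        if ga.intersects(gb):
            d = 0.0
        best = min(best, d)
    return best


def _translate_stack(s: ContourStack, dy_of_z, name=None) -> ContourStack:
    slices = []
    for sl in s.slices:
        dy = float(dy_of_z(sl.z))
        polys = [p + np.array([0.0, dy]) for p in sl.polygons]
        slices.append(ContourSlice(sl.z, polys))
    return ContourStack(name or s.name, slices, s.slice_spacing)


def make_phantom(p: PhantomParams | None = None) -> dict:
    """Pre-implant structure set: CTV, rectum and bladder contour stacks.

    The rectum is placed posterior to the CTV and then shifted so the
    measured minimum slice-wise gap equals the requested one (to contour
    precision). Identical parameters (including seed) give identical
    structures.
    """
    p = PhantomParams() if p is None else p
    rng = np.random.default_rng(p.seed)
    h = p.slice_spacing
    ax, ay, az = p.ctv_semi_axes
    zc = 0.0

    z_lo = zc - p.rectum_length / 2
    z_hi = zc + p.rectum_length / 2
    zs = np.arange(math.floor(z_lo / h), math.ceil(z_hi / h) + 1) * h

    # CTV: ellipsoid cross-sections
    ctv_slices = []
    for z in zs:
        u = (z - zc) / az
        if abs(u) >= 1:
            continue
        s = math.sqrt(1 - u * u)
        if ax * s < 2.0:
            continue
        ctv_slices.append(ContourSlice(z, [_ellipse(0.0, 0.0, ax * s, ay * s)]))
    ctv = ContourStack("CTV", ctv_slices, h)

    # rectum: gently bowed tube with mild per-slice radius irregularity
    jitter = rng.normal(0.0, p.shape_jitter, size=len(zs))
    jitter = ndimage.uniform_filter1d(jitter, size=7, mode="nearest")
    y0 = ay + p.rectum_radius + p.gap + 2.0

    def rectum_stack(y_offset):
        slices = []
        for z, j in zip(zs, jitter):
            if not (z_lo - 1e-9 <= z <= z_hi + 1e-9):
                continue
            cx = p.rectum_curvature * math.sin(math.pi * (z - z_lo) / p.rectum_length)
            r = p.rectum_radius * (1.0 + j)
            slices.append(ContourSlice(z, [_ellipse(cx, y_offset, r, r)]))
        return ContourStack("rectum", slices, h)

    # two-pass placement: measure the realized gap, then shift to match
    rectum = rectum_stack(y0)
    for _ in range(4):
        d = _min_slice_distance(ctv, rectum)
        if d == 0.0 and p.gap > 0:
            y0 += 1.0
            rectum = rectum_stack(y0)
            continue
        if abs(d - p.gap) <= 0.05:
            break
        y0 += p.gap - d
        rectum = rectum_stack(y0)
    d = _min_slice_distance(ctv, rectum)
    if abs(d - p.gap) > 0.5:
        raise ValueError(
            f"could not realize requested CTV-rectum gap {p.gap} mm "
            f"(achieved {d:.2f} mm)"
        )

    # bladder: sphere anterior-superior to the CTV
    rb = p.bladder_radius
    bz = zc + az * 0.5 + rb * 0.4
    by = -(ay + rb * 0.6)
    bladder_slices = []
    for z in zs:
        u = (z - bz) / rb
        if abs(u) >= 1:
            continue
        s = math.sqrt(1 - u * u)
        if rb * s < 2.0:
            continue
        bladder_slices.append(ContourSlice(z, [_ellipse(0.0, by, rb * s, rb * s)]))
    bladder = ContourStack("bladder", bladder_slices, h)

    return {"ctv": ctv, "rectum": rectum, "bladder": bladder}


def apply_spacer(s: dict, sp: SpacerParams | None = None) -> dict:
    """Post-implant structure set: displaced rectum plus spacer structure.

    The rectum moves posteriorly (+y) by a raised-cosine profile centred on
    the CTV mid-slice; its volume is conserved exactly (pure translation per
    slice). The spacer structure fills the vacated space between the
    original and displaced rectum positions. Zero displacement returns the
    input structures unchanged (no spacer volume).
    """
    sp = SpacerParams() if sp is None else sp
    ctv, rectum = s["ctv"], s["rectum"]
    czs = ctv.z_positions
    zc = (czs.min() + czs.max()) / 2
    half = (czs.max() - czs.min()) / 2 + sp.taper_extent

    def profile(z):
        u = (z - zc) / half
        if abs(u) >= 1:
            return 0.0
        return sp.max_displacement * math.cos(math.pi * u / 2) ** 2

    displaced = _translate_stack(rectum, profile, name="rectum")

    soh_slices = []
    if sp.max_displacement > 0:
        for sl in rectum.slices:
            d = profile(sl.z)
            if d <= 0 or not sl.polygons:
                continue
            base = slice_geometry(sl.polygons)
            sweep = shapely.unary_union(
                [affinity.translate(base, yoff=t) for t in np.linspace(0.0, d, 6)]
            )
            soh = sweep.difference(affinity.translate(base, yoff=d))
            polys = geometry_to_polygons(soh)
            if polys:
                soh_slices.append(ContourSlice(sl.z, polys))
    out = dict(s)
    out["rectum"] = displaced
    out["soh"] = ContourStack("SOH", soh_slices, rectum.slice_spacing)
    return out


def surrogate_dose(
    s: dict,
    prescription: float = 60.0,
    penumbra_width: float = 8.0,
    grid_spacing: tuple = (2.0, 2.0, None),
    cfg: StructureRecipeConfig | None = None,
    margins: MarginSpec | None = None,
) -> DoseGrid:
    """Deterministic surrogate dose: prescription in the PTV, sigmoid falloff.

    Dose equals the prescription inside the PTV and decays with the
    Euclidean distance d to the PTV surface as P / (1 + exp(k (d - d0)))
    with k set so the 80 % -> 20 % falloff spans ``penumbra_width`` mm and
    d0 anchored at 95 % of prescription on the PTV surface. The PTV is
    built from the CTV with the standard margins when absent.
    """
    cfg = StructureRecipeConfig() if cfg is None else cfg
    ptv = s.get("ptv")
    if ptv is None:
        if "ctv" not in s:
            raise KeyError("surrogate_dose needs a 'ptv' or 'ctv' structure")
        ptv = geometry.expand_margin(s["ctv"], margins, cfg, name="PTV")

    boxes = [st.bounding_box() for st in s.values() if not st.is_empty]
    boxes.append(ptv.bounding_box())
    xmin = min(b[0][0] for b in boxes) - 15.0
    ymin = min(b[0][1] for b in boxes) - 15.0
    zmin = min(b[0][2] for b in boxes)
    xmax = max(b[1][0] for b in boxes) + 15.0
    ymax = max(b[1][1] for b in boxes) + 15.0
    zmax = max(b[1][2] for b in boxes)

    dx, dy, dz = grid_spacing
    dz = ptv.slice_spacing if dz is None else dz
    nx = int(math.ceil((xmax - xmin) / dx)) + 1
    ny = int(math.ceil((ymax - ymin) / dy)) + 1
    nz = int(round((zmax - zmin) / dz)) + 1
    origin = (xmin, ymin, zmin)

    xs = xmin + np.arange(nx) * dx
    ys = ymin + np.arange(ny) * dy
    gx, gy = np.meshgrid(xs, ys)
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for iz in range(nz):
        z = zmin + iz * dz
        sl = ptv.slice_at(z, tol=ptv.slice_spacing / 2)
        if sl is None or not sl.polygons:
            continue
        geom = slice_geometry(sl.polygons)
        shapely.prepare(geom)
        mask[iz] = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(ny, nx)
    if not mask.any():
        raise ValueError("PTV does not intersect the dose grid")

    dist = ndimage.distance_transform_edt(~mask, sampling=(dz, dy, dx))
    k = math.log(16.0) / penumbra_width
    d0 = math.log(19.0) / k  # 95 % of prescription at the PTV surface
    dose = prescription / (1.0 + np.exp(k * (dist - d0)))
    dose[mask] = prescription
    return DoseGrid(origin=origin, spacing=(dx, dy, dz), values=dose)


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort generator configuration.

    In "model" mode, features are drawn from distributions calibrated to the
    published cohort marginals (log-normal volumes and overlap fractions,
    right-skewed as the printed max/mean ratios imply; normal distances;
    all truncated at the printed min/max) and endpoints follow the published
    linear models with Gaussian noise matched to the printed R^2 via
    sigma^2 = Var(yhat) (1 - R^2) / R^2. In "geometric" mode, endpoints are
    measured by running phantoms through the full geometry + surrogate-dose
    pipeline.

    ``distance_overlap_corr`` is a Gaussian-copula correlation coupling the
    rectum-CTV distance (negatively) to the normalized rectum-in-PTV
    overlap; only the marginals are published, so this coupling is an
    explicit modelling assumption.
    """

    n: int = 21
    mode: str = "model"
    seed: int = 0
    distance_overlap_corr: float = -0.4
    spacer_displacement_mean: float = 10.0
    spacer_displacement_sd: float = 2.0

    def __post_init__(self):
        if self.mode not in ("model", "geometric"):
            raise ValueError("mode must be 'model' or 'geometric'")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not -1 < self.distance_overlap_corr < 1:
            raise ValueError("copula correlation must be in (-1, 1)")


def _lognormal_params(mean: float, sd: float) -> tuple:
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2, math.sqrt(s2)


def _trunc_lognormal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    mu, sigma = _lognormal_params(mean, sd)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=2 * (size - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _lognormal_from_normal_scores(z, mean, sd, lo, hi) -> np.ndarray:
    """Map standard-normal scores through a truncated log-normal marginal."""
    from scipy import stats

    mu, sigma = _lognormal_params(mean, sd)
    a = (math.log(lo) - mu) / sigma
    b = (math.log(hi) - mu) / sigma
    u = stats.norm.cdf(z)
    # inverse CDF of the truncated normal on the log scale
    q = stats.norm.cdf(a) + u * (stats.norm.cdf(b) - stats.norm.cdf(a))
    return np.exp(mu + sigma * stats.norm.ppf(q))


def _trunc_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _model_mode_cohort(c: CohortSimConfig) -> pd.DataFrame:
    from .decision import load_published_models

    reg = load_published_models()
    fs = reg.feature_summary()
    rng = np.random.default_rng(c.seed)
    n = c.n

    rectum = _trunc_lognormal(rng, *fs.loc["rectum_vol_cc", ["mean", "sd", "min", "max"]], n)
    ctv = _trunc_lognormal(rng, *fs.loc["ctv_vol_cc", ["mean", "sd", "min", "max"]], n)
    wall_ratio = _trunc_normal(rng, 0.45, 0.07, 0.30, 0.70, n)
    rw = rectum * wall_ratio

    # Gaussian copula: rectum-CTV distance vs normalized overlap
    rho = c.distance_overlap_corr
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    from scipy import stats

    d = fs.loc["rw_to_ctv_cm"]
    a, b = (d["min"] - d["mean"]) / d["sd"], (d["max"] - d["mean"]) / d["sd"]
    rw_to_ctv = stats.truncnorm.ppf(stats.norm.cdf(z1), a, b, loc=d["mean"], scale=d["sd"])
    o = fs.loc["norm_rinptv_pct"]
    norm_rinptv = _lognormal_from_normal_scores(z2, o["mean"], o["sd"], o["min"], o["max"])

    df = pd.DataFrame(
        {
            "patient_id": [f"sim{c.seed:04d}-{i:03d}" for i in range(n)],
            "rectum_vol_cc": rectum,
            "rw_vol_cc": rw,
            "ctv_vol_cc": ctv,
            "norm_ctv_pct": 100.0 * ctv / rectum,
            "rinptv_cc": norm_rinptv * rectum / 100.0,
            "norm_rinptv_pct": norm_rinptv,
            "rw_to_ctv_cm": rw_to_ctv,
            "rw_to_ctv_cubed_cc": rw_to_ctv**3,
            "rw_to_ctv_inv_cubed": rw_to_ctv**-3.0,
        }
    )

    for dependent in ("delta_rv55_pct", "pre_rv55_pct"):
        model = reg.model(dependent, model_choice=2)
        stats_pub = reg.model_stats(dependent, model_choice=2)
        yhat = model.predict_frame(df)
        r2 = stats_pub["r_squared"]
        sigma = math.sqrt(max(np.var(yhat), 1e-12) * (1 - r2) / r2)
        df[dependent] = yhat + rng.normal(0.0, sigma, size=n)
    return df


def _geometric_mode_cohort(c: CohortSimConfig) -> pd.DataFrame:
    rng = np.random.default_rng(c.seed)
    cfg = StructureRecipeConfig()
    rows = []
    for i in range(c.n):
        rectum_vol = _trunc_lognormal(rng, 79.2, 32.1, 35.5, 149.7, 1)[0]
        ctv_vol = _trunc_lognormal(rng, 39.9, 17.2, 24.6, 91.5, 1)[0]
        length = float(rng.uniform(95.0, 125.0))
        radius = math.sqrt(rectum_vol * 1000.0 / (math.pi * length))
        # ellipsoid with mild anisotropy, scaled to the drawn CTV volume
        shape = np.array([1.0, 0.85, 1.0]) * rng.uniform(0.95, 1.05, size=3)
        scale = (ctv_vol * 1000.0 * 3 / (4 * math.pi * np.prod(shape))) ** (1 / 3)
        semi = tuple(shape * scale)
        gap = float(_trunc_lognormal(rng, 2.5, 2.0, 0.3, 10.0, 1)[0])
        params = PhantomParams(
            ctv_semi_axes=semi,
            rectum_radius=radius,
            rectum_length=length,
            gap=gap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pre = make_phantom(params)
        disp = float(
            np.clip(
                rng.normal(c.spacer_displacement_mean, c.spacer_displacement_sd),
                0.0,
                None,
            )
        )
        post = apply_spacer(pre, SpacerParams(max_displacement=disp))
        fv = extract_features(pre, cfg, patient_id=f"sim{c.seed:04d}-{i:03d}")
        pre_dose = surrogate_dose(pre, cfg=cfg)
        post_dose = surrogate_dose(post, cfg=cfg)
        metrics = paired_metrics(pre_dose, post_dose, pre["rectum"], post["rectum"])
        row = fv.as_dict()
        row["delta_rv55_pct"] = metrics.delta_rv55
        row["pre_rv55_pct"] = metrics.pre_rv55
        rows.append(row)
    return pd.DataFrame(rows)[["patient_id"] + FEATURE_COLUMNS + ENDPOINT_COLUMNS]


def simulate_cohort(c: CohortSimConfig | None = None) -> pd.DataFrame:
    """Simulate a cohort table with features and endpoints (see class doc)."""
    c = CohortSimConfig() if c is None else c
    if c.mode == "model":
        return _model_mode_cohort(c)
    return _geometric_mode_cohort(c)
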