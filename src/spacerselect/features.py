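"""Per-patient geometric feature extraction from a pre-implant structure set.

The feature vector mirrors the independent metrics of the published cohort
summary: absolute volumes (rectum, rectal wall, CTV, rectum-in-PTV), volumes
normalized by the *whole rectum* volume (in percent), and the mean slice-wise
Hausdorff distance between the height-limited rectal wall and the CTV
(RWtoCTV, cm) together with its cubed and inverse-cubed transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
import pandas as pd

from . import geometry
from .geometry import ContourStack, MarginSpec, StructureRecipeConfig

__all__ = [
    "FeatureVector",
    "FEATURE_COLUMNS",
    "ENDPOINT_COLUMNS",
    "extract_features",
    "features_to_frame",
    "summarize_cohort",
]

#: canonical cohort-table feature columns, in serialization order
FEATURE_COLUMNS = [
    "rectum_vol_cc",
    "rw_vol_cc",
    "ctv_vol_cc",
    "norm_ctv_pct",
    "rinptv_cc",
    "norm_rinptv_pct",
    "rw_to_ctv_cm",
    "rw_to_ctv_cubed_cc",
    "rw_to_ctv_inv_cubed",
]

#: endpoint columns (optional until measured or simulated)
ENDPOINT_COLUMNS = ["delta_rv55_pct", "pre_rv55_pct"]

#: structure-set roles consumed here; PTV/RW/RW17.5 are built on demand
REQUIRED_ROLES = ("rectum", "ctv")


@dataclass(frozen=True)
class FeatureVector:
    """Independent geometric metrics for one patient.

    Normalized metrics are percentages of the whole rectum volume;
    rw_to_ctv transforms are in cm^3 (cubed) and cm^-3 (inverse cubed).
    """

    patient_id: str
    rectum_vol_cc: float
    rw_vol_cc: float
    ctv_vol_cc: float
    norm_ctv_pct: float
    rinptv_cc: float
    norm_rinptv_pct: float
    rw_to_ctv_cm: float
    rw_to_ctv_cubed_cc: float
    rw_to_ctv_inv_cubed: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def extract_features(
    structs: Mapping[str, ContourStack],
    cfg: StructureRecipeConfig | None = None,
    margins: MarginSpec | None = None,
    patient_id: str = "",
) -> FeatureVector:
    """Assemble the per-patient feature vector from a pre-implant structure set.

    ``structs`` maps canonical roles to contour stacks; 'rectum' and 'ctv'
    are required, while 'ptv', 'rw' and 'rw17' are built with the standard
    recipes (margin expansion, 3 mm inner wall, 17.5 mm height limiting)
    when absent. Deterministic for a fixed configuration.
    """
    cfg = StructureRecipeConfig() if cfg is None else cfg
    missing = [r for r in REQUIRED_ROLES if r not in structs]
    if missing:
        raise KeyError(f"structure set is missing required roles: {missing}")
    rectum, ctv = structs["rectum"], structs["ctv"]

    ptv = structs.get("ptv") or geometry.expand_margin(ctv, margins, cfg, name="PTV")
    rw = structs.get("rw") or geometry.make_wall(rectum, cfg, name="RW")
    rw17 = structs.get("rw17") or geometry.height_limit(rw, ptv, cfg, name="RW17.5")

    rectum_vol = geometry.volume(rectum)
    rw_vol = geometry.volume(rw)
    ctv_vol = geometry.volume(ctv)
    rinptv = geometry.overlap_volume(ptv, rectum)
    d_cm = geometry.mean_slice_hausdorff(rw17, ctv)

    return FeatureVector(
        patient_id=str(patient_id),
        rectum_vol_cc=rectum_vol,
        rw_vol_cc=rw_vol,
        ctv_vol_cc=ctv_vol,
        norm_ctv_pct=100.0 * ctv_vol / rectum_vol,
        rinptv_cc=rinptv,
        norm_rinptv_pct=100.0 * rinptv / rectum_vol,
        rw_to_ctv_cm=d_cm,
        rw_to_ctv_cubed_cc=d_cm**3,
        rw_to_ctv_inv_cubed=d_cm**-3,
    )


def features_to_frame(rows, endpoints: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort table from FeatureVectors (plus optional endpoint columns).

    Patient ids must be unique; the result uses the canonical column order
    consumed by the regression and decision modules.
    """
    recs = [r.as_dict() if isinstance(r, FeatureVector) else dict(r) for r in rows]
    df = pd.DataFrame.from_records(recs)
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {dupes}")
    cols = ["patient_id"] + FEATURE_COLUMNS
    df = df[cols]
    if endpoints is not None:
        df = df.join(endpoints[ENDPOINT_COLUMNS].reset_index(drop=True))
    return df


def summarize_cohort(t: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1), min and max per numeric cohort column."""
    if len(t) < 2:
        raise ValueError("cohort summary requires at least 2 rows")
    num = t.select_dtypes(include=[np.number])
    return pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "min": num.min(),
            "max": num.max(),
        }
    )
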