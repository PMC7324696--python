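"""File formats and run configuration.

Readers for DICOM RT Structure Sets and RT Dose files (via pydicom), plus a
plain-JSON mirror of both so pipelines are testable and archivable without
binary data:

structure JSON::

    {"name": ..., "slice_spacing_mm": ...,
     "slices": [{"z_mm": ..., "polygons": [[[x, y], ...], ...]}, ...]}

Polygons are written with explicit closure (last vertex repeats the first);
DICOM's implicit closure is normalized on read. Dose JSON mirrors the
DoseGrid fields. Cohort tables are CSV with the canonical headers defined in
:mod:`spacerselect.features`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decision import DecisionConfig
from .dvh import DoseGrid, DVHCurve
from .features import ENDPOINT_COLUMNS, FEATURE_COLUMNS
from .geometry import ContourSlice, ContourStack, StructureRecipeConfig
from .regression import StepwiseConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "FormatError",
    "read_rtstruct",
    "read_rtdose",
    "read_structure_json",
    "write_structure_json",
    "read_dose_json",
    "write_dose_json",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_dvh_csv",
    "config_hash",
]


class FormatError(ValueError):
    """Malformed or unsupported input file."""


# ---------------------------------------------------------------------------
# internal JSON formats

def _stack_to_obj(s: ContourStack) -> dict:
    return {
        "name": s.name,
        "slice_spacing_mm": s.slice_spacing,
        "slices": [
            {
                "z_mm": sl.z,
                "polygons": [
                    np.vstack([p, p[:1]]).tolist() for p in sl.polygons  # explicit closure
                ],
            }
            for sl in s.slices
        ],
    }


def _obj_to_stack(obj: dict) -> ContourStack:
    slices = [
        ContourSlice(sl["z_mm"], [np.asarray(p, dtype=float) for p in sl["polygons"]])
        for sl in obj["slices"]
    ]
    return ContourStack(obj["name"], slices, obj["slice_spacing_mm"])


def write_structure_json(path, structures) -> None:
    """Write a structure set ({role: ContourStack}) to JSON."""
    payload = {"structures": {role: _stack_to_obj(s) for role, s in structures.items()}}
    Path(path).write_text(json.dumps(payload))


def read_structure_json(path) -> dict:
    """Read a structure set from the internal JSON format."""
    obj = json.loads(Path(path).read_text())
    if "structures" not in obj:
        raise FormatError(f"{path}: not a structure-set JSON file")
    return {role: _obj_to_stack(o) for role, o in obj["structures"].items()}


def write_dose_json(path, dose: DoseGrid) -> None:
    payload = {
        "origin_mm": list(dose.origin),
        "spacing_mm": list(dose.spacing),
        "values_gy": dose.values.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_dose_json(path) -> DoseGrid:
    obj = json.loads(Path(path).read_text())
    try:
        return DoseGrid(obj["origin_mm"], obj["spacing_mm"], np.asarray(obj["values_gy"]))
    except KeyError as e:
        raise FormatError(f"{path}: missing dose field {e}") from e


# ---------------------------------------------------------------------------
# DICOM readers (read-only; minimal fixture writers live in the test suite)

def read_rtstruct(path, name_map: dict | None = None) -> dict:
    """Read a DICOM RT Structure Set into {name: ContourStack}.

    Contours must be closed planar (constant z per contour); z positions are
    sorted and the slice spacing inferred as the smallest positive z gap.
    ``name_map`` renames ROIs to canonical roles (e.g. "Rectum_AW" ->
    "rectum"); unmapped ROIs keep their DICOM names.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTSTRUCT" or "ROIContourSequence" not in ds:
        raise FormatError(f"{path}: not an RT Structure Set with contours")
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    name_map = name_map or {}
    out = {}
    for rc in ds.ROIContourSequence:
        name = roi_names.get(int(rc.ReferencedROINumber), f"ROI{rc.ReferencedROINumber}")
        name = name_map.get(name, name)
        by_z: dict = {}
        for contour in getattr(rc, "ContourSequence", []):
            geom_type = getattr(contour, "ContourGeometricType", "CLOSED_PLANAR")
            if geom_type not in ("CLOSED_PLANAR", "CLOSEDPLANAR_XOR"):
                raise FormatError(
                    f"{path}: unsupported contour geometry '{geom_type}' in '{name}'"
                )
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            if np.ptp(pts[:, 2]) > 1e-3:
                raise FormatError(f"{path}: non-planar contour in ROI '{name}'")
            z = round(float(pts[0, 2]), 3)
            by_z.setdefault(z, []).append(pts[:, :2])
        if not by_z:
            logger.warning("RTSTRUCT ROI '%s' has no contours; skipped", name)
            continue
        zs = sorted(by_z)
        spacing = min(np.diff(zs)) if len(zs) > 1 else 1.0
        out[name] = ContourStack(
            name, [(z, by_z[z]) for z in zs], float(spacing)
        )
    if not out:
        logger.warning("RTSTRUCT %s contains no populated ROIs", path)
    return out


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose file into a DoseGrid (Gy, mm).

    DoseGridScaling is applied; the grid must have uniform slice offsets.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{path}: not an RT Dose file")
    if "DoseGridScaling" not in ds:
        raise FormatError(f"{path}: missing DoseGridScaling")
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if values.ndim == 2:
        values = values[None]
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        dzs = np.diff(offsets)
        if not np.allclose(dzs, dzs[0], atol=1e-6):
            raise FormatError(f"{path}: non-uniform slice spacing is unsupported")
        dz = float(dzs[0])
    else:
        dz = 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # (dy, dx)
    x0, y0, z0 = (float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(origin=(x0, y0, z0 + float(offsets[0])), spacing=(col_sp, row_sp, dz), values=values)


# ---------------------------------------------------------------------------
# cohort tables and DVH export

CANONICAL_COLUMNS = ["patient_id"] + FEATURE_COLUMNS + ENDPOINT_COLUMNS


def write_cohort_csv(path, t: pd.DataFrame) -> None:
    cols = [c for c in CANONICAL_COLUMNS if c in t.columns]
    t[cols].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["patient_id"] + FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cohort columns {missing}")
    return df


def write_dvh_csv(path, curve: DVHCurve) -> None:
    pd.DataFrame(
        {"dose_gy": curve.dose_edges, "volume_pct": curve.relative_volume}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration

_KNOWN_KEYS = {
    "structures",
    "dose_pre",
    "dose_post",
    "output",
    "structure_names",
    "recipe",
    "stepwise",
    "decision",
    "seed",
    "log_level",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (YAML on disk).

    ``structure_names`` maps clinical labels to canonical roles; when given,
    the roles 'ctv' and 'rectum' must both be mapped. Unknown top-level keys
    are rejected rather than silently ignored.
    """

    structures: str | None = None
    dose_pre: str | None = None
    dose_post: str | None = None
    output: str = "."
    structure_names: dict = field(default_factory=dict)
    recipe: StructureRecipeConfig = field(default_factory=StructureRecipeConfig)
    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs = dict(raw)
        if "recipe" in kwargs:
            kwargs["recipe"] = StructureRecipeConfig(**kwargs["recipe"])
        if "stepwise" in kwargs:
            sw = dict(kwargs["stepwise"])
            if "candidates" in sw:
                sw["candidates"] = tuple(sw["candidates"])
            if "exclusive_groups" in sw:
                sw["exclusive_groups"] = tuple(frozenset(g) for g in sw["exclusive_groups"])
            kwargs["stepwise"] = StepwiseConfig(**sw)
        if "decision" in kwargs:
            kwargs["decision"] = DecisionConfig(**kwargs["decision"])
        cfg = cls(**kwargs)
        if cfg.structure_names:
            roles = set(cfg.structure_names.values())
            if not {"ctv", "rectum"} <= roles:
                raise FormatError(
                    f"{path}: structure_names must map both 'ctv' and 'rectum'"
                )
        return cfg


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
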