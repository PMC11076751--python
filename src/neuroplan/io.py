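"""File formats and run configuration.

Open formats throughout: STL/PLY for meshes, NIfTI for label volumes
(isotropic mm spacing in the affine), a versioned JSON schema for
participant annotations, and plain CSV for metric and comparison tables.
Every table artifact carries the master seed and a hash of the run
configuration in leading ``#`` comment lines so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .errors import SchemaError
from .metrics import AnnotationSet
from .phantom import LabelVolume
from .projection import Quad2D

__all__ = [
    "RunConfig",
    "config_hash",
    "write_mesh",
    "read_mesh",
    "write_volume",
    "read_volume",
    "write_annotation",
    "read_annotation",
    "annotation_to_dict",
    "annotation_from_dict",
    "write_table",
    "read_table",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration; hashed into every output artifact."""

    seed: int = 0
    n_residents: int = 14
    n_interns: int = 24
    raster_pitch_mm: float = 0.25
    standard_margin_mm: float = 10.0
    margin_convention: str = "midpoint-ray"
    voxel_pitch_mm: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.raster_pitch_mm <= 0 or self.voxel_pitch_mm <= 0:
            raise SchemaError("pitches must be positive")
        if self.margin_convention not in ("midpoint-ray", "segment-min"):
            raise SchemaError(f"unknown margin convention {self.margin_convention!r}")


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# meshes and volumes


def write_mesh(mesh: trimesh.Trimesh, path) -> Path:
    path = Path(path)
    mesh.export(path)
    return path


def read_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    try:
        mesh = trimesh.load(path, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise SchemaError(f"cannot parse mesh file {path.name}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise SchemaError(f"mesh file {path.name} contains no triangles")
    return mesh


def write_volume(volume: LabelVolume, path) -> Path:
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] *= volume.pitch
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    img.header.set_zooms((volume.pitch,) * 3)
    nib.save(img, path)
    return path


def read_volume(path) -> LabelVolume:
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # noqa: BLE001
        raise SchemaError(f"cannot parse volume file {path.name}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise SchemaError(f"volume {path.name} is not isotropic: zooms {zooms}")
    labels = np.asarray(img.dataobj).astype(np.int8)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return LabelVolume(labels=labels, pitch=float(zooms[0]), origin=origin)


# ---------------------------------------------------------------------------
# annotations (JSON schema v1)


def annotation_to_dict(ann: AnnotationSet) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "units": "mm",
        "assessment": ann.assessment,
        "layers": dict(ann.layers),
        "elements": {
            "painted": {"ring": [list(map(float, xy)) for xy in np.asarray(ann.painted.exterior.coords)[:-1]]}
            if ann.painted.geom_type == "Polygon"
            else {"rings": [[list(map(float, xy)) for xy in np.asarray(g.exterior.coords)[:-1]] for g in ann.painted.geoms]},
            "linear_incision": [list(map(float, xy)) for xy in ann.linear_incision.coords],
            "u_incision": [list(map(float, xy)) for xy in ann.u_incision.coords],
            "burr_holes": [list(map(float, xy)) for xy in np.asarray(ann.burr_holes)],
            "craniotomy": [list(map(float, xy)) for xy in ann.craniotomy.vertices],
        },
        "meta": dict(ann.meta),
    }


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise SchemaError(msg)


def _coords(obj, name: str, min_len: int) -> np.ndarray:
    _require(isinstance(obj, list) and len(obj) >= min_len, f"{name}: needs >= {min_len} points")
    arr = np.asarray(obj, dtype=float)
    _require(arr.ndim == 2 and arr.shape[1] == 2, f"{name}: points must be 2D [x, y]")
    _require(bool(np.all(np.isfinite(arr))), f"{name}: coordinates must be finite")
    return arr


def annotation_from_dict(doc: dict) -> AnnotationSet:
    _require(isinstance(doc, dict), "annotation document must be a JSON object")
    _require(doc.get("schema_version") == SCHEMA_VERSION, f"schema_version must be {SCHEMA_VERSION}")
    _require(doc.get("units") == "mm", "units: must be 'mm'")
    _require(doc.get("assessment") in ("AA1", "AA2"), "assessment: must be 'AA1' or 'AA2'")
    el = doc.get("elements")
    _require(isinstance(el, dict), "elements: missing or not an object")
    for key in ("painted", "linear_incision", "u_incision", "burr_holes", "craniotomy"):
        _require(key in el, f"elements.{key}: missing")
    painted_el = el["painted"]
    _require(isinstance(painted_el, dict), "elements.painted: must be an object with 'ring' or 'rings'")
    if "ring" in painted_el:
        painted = _coords(painted_el["ring"], "elements.painted.ring", 3)
    else:
        _require("rings" in painted_el, "elements.painted: needs 'ring' or 'rings'")
        from shapely.geometry import MultiPolygon, Polygon

        painted = MultiPolygon(
            [Polygon(_coords(r, "elements.painted.rings[]", 3)) for r in painted_el["rings"]]
        )
    try:
        return AnnotationSet(
            painted=painted,
            linear_incision=_coords(el["linear_incision"], "elements.linear_incision", 2),
            u_incision=_coords(el["u_incision"], "elements.u_incision", 4),
            burr_holes=_coords(el["burr_holes"], "elements.burr_holes", 1),
            craniotomy=Quad2D(_coords(el["craniotomy"], "elements.craniotomy", 4)),
            assessment=doc["assessment"],
            layers=doc.get("layers", {}),
            meta=doc.get("meta", {}),
        )
    except SchemaError:
        raise
    except Exception as exc:  # geometry validation failures -> schema context
        raise SchemaError(f"elements: {exc}") from exc


def write_annotation(ann: AnnotationSet, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(annotation_to_dict(ann), indent=1))
    return path


def read_annotation(path) -> AnnotationSet:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path.name}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        return annotation_from_dict(doc)
    except SchemaError as exc:
        raise SchemaError(f"{path.name}: {exc}") from exc


# ---------------------------------------------------------------------------
# tables


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None, **extra_meta) -> Path:
    """CSV with provenance comment lines (# key: value) before the header."""
    path = Path(path)
    lines = []
    if config is not None:
        lines.append(f"# seed: {config.seed}")
        lines.append(f"# config_hash: {config_hash(config)}")
    for k, v in extra_meta.items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
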