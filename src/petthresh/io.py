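"""Serialization: NIfTI volumes, JSON models/specs/ROIs, CSV record tables.

All writes are atomic (temp file in the destination directory, then
rename), so a failed run never leaves a partial artifact behind.  Units on
disk match the in-memory contract: mm, mm², ml, percent.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .calibration import (
    RECORD_COLUMNS,
    SearchSettings,
    ThresholdRecord,
    frame_to_records,
    records_to_frame,
)
from .phantom import GroundTruth, ImageVolume, PhantomSpec, Sphere, ground_truth_for
from .regression import ModelPair, SplitModels, ThresholdModel
from .roi import ROISet, SliceROI

__all__ = [
    "ParseError",
    "save_volume",
    "load_volume",
    "save_truth",
    "load_truth",
    "save_spec",
    "load_spec",
    "save_records",
    "load_records",
    "save_models",
    "load_models",
    "save_roi_set",
    "load_roi_set",
    "atomic_write_text",
]


class ParseError(ValueError):
    """A file could not be interpreted; the message names file and field."""


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_json(path: str | Path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2))


def _read_json(path: str | Path):
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ParseError(f"{path}: invalid JSON at line {err.lineno}: {err.msg}") from err


# ---------------------------------------------------------------------------
# volumes


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write as NIfTI with the spacing on the affine diagonal and the
    origin in the translation column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.voxel_spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".nii")
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ParseError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ImageVolume(data, zooms, origin)


# ---------------------------------------------------------------------------
# ground truth + phantom spec


def _sphere_to_dict(s: Sphere) -> dict:
    return {
        "center_mm": list(s.center),
        "internal_diameter_mm": s.internal_diameter,
        "activity_kbq_ml": s.activity,
    }


def _sphere_from_dict(d: dict, path) -> Sphere:
    try:
        return Sphere(
            center=tuple(d["center_mm"]),
            internal_diameter=float(d["internal_diameter_mm"]),
            activity=float(d["activity_kbq_ml"]),
        )
    except KeyError as err:
        raise ParseError(f"{path}: sphere entry missing field {err}") from err


def save_truth(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar: spheres and grid geometry; the per-slice areas and
    label mask are reconstructed analytically on load."""
    _atomic_json(
        path,
        {
            "spheres": [_sphere_to_dict(s) for s in truth.spheres],
            "voxel_spacing_mm": list(truth.voxel_spacing),
            "grid_shape": list(truth.label_mask.shape),
            "origin_mm": list(truth.origin),
        },
    )


def load_truth(path: str | Path) -> GroundTruth:
    d = _read_json(path)
    try:
        return ground_truth_for(
            tuple(_sphere_from_dict(s, path) for s in d["spheres"]),
            tuple(d["voxel_spacing_mm"]),
            tuple(d["grid_shape"]),
            tuple(d.get("origin_mm", (0.0, 0.0, 0.0))),
        )
    except KeyError as err:
        raise ParseError(f"{path}: missing field {err}") from err


def save_spec(spec: PhantomSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    d["spheres"] = [_sphere_to_dict(s) for s in spec.spheres]
    _atomic_json(path, d)


def load_spec(path: str | Path) -> PhantomSpec:
    d = _read_json(path)
    try:
        spheres = tuple(_sphere_from_dict(s, path) for s in d.pop("spheres", []))
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return PhantomSpec(spheres=spheres, **d)
    except (KeyError, TypeError) as err:
        raise ParseError(f"{path}: invalid phantom spec: {err}") from err


# ---------------------------------------------------------------------------
# calibration records


def save_records(records, path: str | Path) -> None:
    df = records_to_frame(records)[RECORD_COLUMNS]
    atomic_write_text(path, df.to_csv(index=False))


def load_records(path: str | Path) -> list[ThresholdRecord]:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise ParseError(f"{path}: {err}") from err
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return frame_to_records(df)


# ---------------------------------------------------------------------------
# models


def _model_to_dict(m: ThresholdModel) -> dict:
    return {
        "form": m.form,
        "coefficients": m.coefficients,
        "area_split_mm2": m.area_split_mm2,
        "ranges": {k: list(v) for k, v in m.ranges.items()},
        "provenance": m.provenance,
        "r2_adj": m.r2_adj,
        "scheme": m.scheme,
    }


def _model_from_dict(d: dict, path) -> ThresholdModel:
    try:
        return ThresholdModel(
            form=d["form"],
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            area_split_mm2=float(d.get("area_split_mm2", 133.0)),
            ranges={k: tuple(v) for k, v in d.get("ranges", {}).items()},
            provenance=d.get("provenance", "fitted"),
            r2_adj=d.get("r2_adj"),
            scheme=d.get("scheme"),
        )
    except (KeyError, ValueError) as err:
        raise ParseError(f"{path}: invalid model: {err}") from err


def _pair_to_dict(p: ModelPair) -> dict:
    return {
        "small": _model_to_dict(p.small),
        "large": _model_to_dict(p.large),
        "area_split_mm2": p.area_split_mm2,
    }


def _pair_from_dict(d: dict, path) -> ModelPair:
    try:
        return ModelPair(
            small=_model_from_dict(d["small"], path),
            large=_model_from_dict(d["large"], path),
            area_split_mm2=float(d.get("area_split_mm2", 133.0)),
        )
    except KeyError as err:
        raise ParseError(f"{path}: model pair missing {err}") from err


def save_models(models: ThresholdModel | ModelPair | SplitModels, path: str | Path) -> None:
    """Write a single model, a small/large pair, or a full split-model set
    (pooled + per-scheme) as JSON."""
    if isinstance(models, ThresholdModel):
        obj = {"kind": "model", "model": _model_to_dict(models)}
    elif isinstance(models, ModelPair):
        obj = {"kind": "pair", "pair": _pair_to_dict(models)}
    elif isinstance(models, SplitModels):
        obj = {
            "kind": "split",
            "pooled": _pair_to_dict(models.pooled) if models.pooled else None,
            "per_scheme": [
                {"iterations": k[0], "fwhm_mm": k[1], "pair": _pair_to_dict(v)}
                for k, v in sorted(models.per_scheme.items())
            ],
        }
    else:
        raise TypeError(f"cannot serialize {type(models).__name__}")
    _atomic_json(path, obj)


def load_models(path: str | Path) -> ThresholdModel | ModelPair | SplitModels:
    d = _read_json(path)
    kind = d.get("kind")
    if kind == "model":
        return _model_from_dict(d["model"], path)
    if kind == "pair":
        return _pair_from_dict(d["pair"], path)
    if kind == "split":
        return SplitModels(
            pooled=_pair_from_dict(d["pooled"], path) if d.get("pooled") else None,
            per_scheme={
                (int(e["iterations"]), float(e["fwhm_mm"])): _pair_from_dict(e["pair"], path)
                for e in d["per_scheme"]
            },
        )
    raise ParseError(f"{path}: unknown model file kind {kind!r}")


# ---------------------------------------------------------------------------
# ROI sets


def save_roi_set(rois: ROISet, path: str | Path) -> None:
    _atomic_json(
        path,
        {
            "rois": [
                {
                    "center_mm": list(r.center),
                    "diameter_mm": r.diameter,
                    "slice_index": r.slice_index,
                    "role": r.role,
                }
                for r in rois
            ]
        },
    )


def load_roi_set(path: str | Path) -> ROISet:
    d = _read_json(path)
    try:
        return ROISet(
            tuple(
                SliceROI(
                    center=tuple(r["center_mm"]),
                    diameter=float(r["diameter_mm"]),
                    slice_index=int(r["slice_index"]),
                    role=r.get("role", "target"),
                )
                for r in d["rois"]
            )
        )
    except KeyError as err:
        raise ParseError(f"{path}: ROI entry missing {err}") from err
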