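"""NIfTI, CSV and JSON input/output with explicit geometry handling.

Volumes and masks are stored as NIfTI-1 (.nii/.nii.gz); masks as unsigned
8-bit.  Overlap results are stored as one CSV row per (case, method,
A-threshold, R-threshold) with floats at 12 significant digits.  Transforms
are stored as JSON (rigid: 6 parameters + center) next to a NIfTI vector
field for deformations.  Geometry is never silently defaulted: a volume
without usable spacing is an error, not 1 mm.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .overlap import INDEX_NAMES, OverlapResult
from .transforms import DeformationField, RigidTransform
from .volumes import GeometryError, ScalarVolume, VoiMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_overlap_table",
    "read_overlap_table",
    "write_rigid_transform",
    "read_rigid_transform",
    "write_deformation_field",
    "read_deformation_field",
    "write_case",
]

OVERLAP_KEY_COLUMNS = ["case_id", "method", "a_label", "r_label"]
OVERLAP_COLUMNS = OVERLAP_KEY_COLUMNS[:1] + ["position_group"] + OVERLAP_KEY_COLUMNS[1:] + [
    *INDEX_NAMES,
    "vol_a_cc",
    "vol_r_cc",
    "vol_common_cc",
]


def _read_sitk(path) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise GeometryError(
            f"{path.name}: expected a 3D volume, got {img.GetDimension()}D"
        )
    return img


def read_volume(path, modality: str) -> ScalarVolume:
    """Read a 3D NIfTI scalar volume; errors on 4D input or bad geometry."""
    return ScalarVolume.from_sitk(_read_sitk(path), modality=modality)


def write_volume(vol: ScalarVolume, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(vol.to_sitk(), str(path))


def read_mask(path, label: str, threshold_fraction: float | None = None) -> VoiMask:
    img = _read_sitk(path)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoiMask(
        mask=data > 0,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
        label=label,
        threshold_fraction=threshold_fraction,
    )


def write_mask(mask: VoiMask, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(mask.to_sitk(), str(path))


def overlap_results_to_frame(results: list[OverlapResult]) -> pd.DataFrame:
    if not results:
        raise ValueError("no overlap results to tabulate")
    df = pd.DataFrame([asdict(r) for r in results])
    return df[OVERLAP_COLUMNS]


def write_overlap_table(results, path) -> None:
    """Write overlap results as CSV; one row per (case, method, A, R) pair.

    Accepts a list of OverlapResult or an equivalently shaped DataFrame.
    Duplicate (case, method, thresholds) keys are an error.
    """
    if isinstance(results, pd.DataFrame):
        if results.empty:
            raise ValueError("no overlap results to tabulate")
        df = results[OVERLAP_COLUMNS]
    else:
        df = overlap_results_to_frame(list(results))
    dup = df.duplicated(subset=OVERLAP_KEY_COLUMNS)
    if dup.any():
        first = df.loc[dup.idxmax(), OVERLAP_KEY_COLUMNS].tolist()
        raise ValueError(f"duplicate overlap key {tuple(first)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def read_overlap_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(OVERLAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"overlap table {path} missing columns {sorted(missing)}")
    return df


def write_rigid_transform(tfm: RigidTransform, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(tfm.to_dict(), fh, indent=2)


def read_rigid_transform(path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_dict(json.load(fh))


def write_deformation_field(field: DeformationField, dir_path, stem: str = "deformation") -> None:
    """Store a deformation as a NIfTI vector field plus a JSON sidecar with
    the rigid initialization and control spacing."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(field.to_sitk_image(), str(dir_path / f"{stem}.nii.gz"))
    sidecar = {
        "control_spacing_mm": field.control_spacing_mm,
        "init": field.init.to_dict(),
    }
    with open(dir_path / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_deformation_field(dir_path, stem: str = "deformation") -> DeformationField:
    dir_path = Path(dir_path)
    img = sitk.ReadImage(str(dir_path / f"{stem}.nii.gz"))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise GeometryError(f"{stem}.nii.gz is not a 3-component vector field")
    with open(dir_path / f"{stem}.json") as fh:
        sidecar = json.load(fh)
    return DeformationField(
        displacement=arr.transpose(2, 1, 0, 3),
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
        control_spacing_mm=sidecar["control_spacing_mm"],
        init=RigidTransform.from_dict(sidecar["init"]),
    )


def write_case(case, dir_path) -> None:
    """Write one phantom case: four NIfTI volumes, ground-truth masks, and a
    JSON sidecar with the true transforms and the generating config."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_volume(case.pet_a, dir_path / "pet_a.nii.gz")
    write_volume(case.ct_a, dir_path / "ct_a.nii.gz")
    write_volume(case.pet_r, dir_path / "pet_r.nii.gz")
    write_volume(case.ct_r, dir_path / "ct_r.nii.gz")
    write_mask(case.true_lesion_a, dir_path / "true_lesion_a.nii.gz")
    write_mask(case.true_lesion_r, dir_path / "true_lesion_r.nii.gz")
    write_deformation_field(case.true_deformation, dir_path, stem="true_deformation")
    sidecar = {
        "case_id": case.case_id,
        "position_group": case.position_group,
        "true_rigid": case.true_rigid.to_dict(),
        "config": asdict(case.config),
    }
    with open(dir_path / "case.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
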