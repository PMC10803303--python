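"""NIfTI persistence for cases plus the per-cohort CSV sidecar."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BinaryMask, CaseRecord, VolumeImage

__all__ = ["write_nifti", "read_nifti", "write_cohort", "read_cohort", "SidecarError"]

SIDECAR = "cases.csv"
_COLUMNS = ["patient_id", "centre_id", "emvi", "cr", "age", "sex", "cT", "cN", "channels"]


class SidecarError(ValueError):
    """Raised when the cohort sidecar table cannot be parsed."""


def _affine(spacing, origin):
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_nifti(case: CaseRecord, directory) -> Path:
    """Write image (4D NIfTI), mask and a sidecar row; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_arr = np.moveaxis(case.image.data, 0, -1)  # (D, H, W, C)
    aff = _affine(case.image.spacing, case.image.origin)
    nib.save(nib.Nifti1Image(img_arr.astype(np.float32), aff),
             directory / f"{case.patient_id}_image.nii.gz")
    nib.save(nib.Nifti1Image(case.mask.data.astype(np.uint8), aff),
             directory / f"{case.patient_id}_mask.nii.gz")

    row = {
        "patient_id": case.patient_id,
        "centre_id": case.centre_id,
        "emvi": case.emvi_label,
        "cr": case.cr_label,
        "age": case.age,
        "sex": case.sex,
        "cT": case.cT,
        "cN": case.cN,
        "channels": "|".join(case.image.channel_names),
    }
    sidecar = directory / SIDECAR
    if sidecar.exists():
        df = _load_sidecar(sidecar)
        df = df[df["patient_id"] != case.patient_id]
        df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    else:
        df = pd.DataFrame([row])
    df.to_csv(sidecar, index=False)
    return directory


def _load_sidecar(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"sidecar table not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "centre_id": str,
                                      "sex": str, "cT": str})
    except Exception as exc:  # malformed CSV
        raise SidecarError(f"could not parse sidecar {path}: {exc}") from exc
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise SidecarError(f"sidecar {path} is missing columns {sorted(missing)}")
    return df


def read_nifti(directory, patient_id: str | None = None) -> CaseRecord:
    """Read one case back. With a single-case directory patient_id is optional."""
    directory = Path(directory)
    df = _load_sidecar(directory / SIDECAR)
    if patient_id is None:
        if len(df) != 1:
            raise ValueError("patient_id required when the sidecar lists several cases")
        row = df.iloc[0]
    else:
        sel = df[df["patient_id"] == patient_id]
        if sel.empty:
            raise FileNotFoundError(f"{patient_id} not present in sidecar")
        row = sel.iloc[0]
    pid = str(row["patient_id"])
    img_path = directory / f"{pid}_image.nii.gz"
    mask_path = directory / f"{pid}_mask.nii.gz"
    if not img_path.exists() or not mask_path.exists():
        raise FileNotFoundError(f"image or mask file missing for {pid}")
    img_nii = nib.load(img_path)
    mask_nii = nib.load(mask_path)
    img_arr = np.asarray(img_nii.dataobj, dtype=np.float32)
    if img_arr.ndim == 3:
        img_arr = img_arr[..., None]
    mask_arr = np.asarray(mask_nii.dataobj)
    if img_arr.shape[:3] != mask_arr.shape:
        raise ValueError(
            f"image grid {img_arr.shape[:3]} does not match mask grid {mask_arr.shape}"
        )
    spacing = tuple(float(s) for s in img_nii.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img_nii.affine[:3, 3])
    channels = tuple(str(row["channels"]).split("|"))
    image = VolumeImage(np.moveaxis(img_arr, -1, 0), channels, spacing, origin)
    mask = BinaryMask(mask_arr, spacing)
    return CaseRecord(
        patient_id=pid,
        centre_id=str(row["centre_id"]),
        image=image,
        mask=mask,
        emvi_label=int(row["emvi"]),
        cr_label=int(row["cr"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        cT=str(row["cT"]),
        cN=int(row["cN"]),
    )


def write_cohort(cases: list[CaseRecord], directory) -> Path:
    directory = Path(directory)
    for case in cases:
        write_nifti(case, directory)
    return directory


def read_cohort(directory) -> list[CaseRecord]:
    directory = Path(directory)
    df = _load_sidecar(directory / SIDECAR)
    return [read_nifti(directory, pid) for pid in df["patient_id"]]
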