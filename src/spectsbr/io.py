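"""Persistence: NIfTI volumes, projection directories, CSV databases, YAML configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantoms import ActivityVolume
from .quantify import SBRRecord
from .reconstruct import ReconVolume
from .simulate import ProjectionSet

DB_COLUMNS = [
    "subject_id", "side", "method", "recon", "camera",
    "sbr", "c_s", "c_ns", "calibrated", "sbr_uncalibrated",
    "age", "sex", "true_sbr",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_activity_volume(vol: ActivityVolume, path) -> None:
    """Write activity and labels as a NIfTI pair (<stem>.nii / <stem>_labels.nii)."""
    path = Path(path)
    aff = _affine(vol.voxel_size_mm)
    nib.save(nib.Nifti1Image(vol.activity.astype(np.float32), aff), str(path))
    labels_path = path.parent / (path.name.replace(".nii", "_labels.nii"))
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), aff), str(labels_path))


def load_activity_volume(path) -> ActivityVolume:
    path = Path(path)
    img = nib.load(str(path))
    labels_path = path.parent / (path.name.replace(".nii", "_labels.nii"))
    lab = nib.load(str(labels_path))
    voxel = float(img.header.get_zooms()[0])
    return ActivityVolume(
        np.asarray(img.dataobj, dtype=np.float64),
        np.asarray(lab.dataobj, dtype=np.int16),
        voxel,
    )


def save_recon_volume(vol: ReconVolume, path) -> None:
    """NIfTI volume plus JSON provenance sidecar."""
    path = Path(path)
    nib.save(
        nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size_mm)),
        str(path),
    )
    sidecar = path.parent / (path.name.replace(".nii", ".json"))
    sidecar.write_text(json.dumps(vol.meta, indent=2, default=str))


def load_recon_volume(path) -> ReconVolume:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.parent / (path.name.replace(".nii", ".json"))
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ReconVolume(
        np.asarray(img.dataobj, dtype=np.float64),
        float(img.header.get_zooms()[0]),
        meta,
    )


def save_projection_set(p: ProjectionSet, directory) -> None:
    """Directory of three NIfTI stacks (ph/sc_l/sc_u) plus a JSON sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    for name in ("ph", "sc_l", "sc_u"):
        nib.save(
            nib.Nifti1Image(getattr(p, name).astype(np.float32), aff),
            str(d / f"{name}.nii"),
        )
    sidecar = {
        "angles": list(map(float, p.angles)),
        "w_ph": p.w_ph,
        "w_sc": p.w_sc,
        "meta": p.meta,
    }
    (d / "scan.json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_projection_set(directory) -> ProjectionSet:
    d = Path(directory)
    sidecar = json.loads((d / "scan.json").read_text())
    arrays = {
        name: np.asarray(nib.load(str(d / f"{name}.nii")).dataobj, dtype=np.float64)
        for name in ("ph", "sc_l", "sc_u")
    }
    return ProjectionSet(
        arrays["ph"], arrays["sc_l"], arrays["sc_u"],
        np.asarray(sidecar["angles"], dtype=float),
        sidecar["w_ph"], sidecar["w_sc"], sidecar.get("meta", {}),
    )


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=DB_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> "list[SBRRecord]":
    records = []
    for row in df.to_dict("records"):
        row = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        row["calibrated"] = bool(row["calibrated"])
        records.append(SBRRecord(**row))
    return records


def save_database_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def load_database_csv(path) -> "list[SBRRecord]":
    return frame_to_records(pd.read_csv(path))


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
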