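"""NIfTI and sidecar I/O helpers (nibabel-backed).

Scalar maps are written as 3-D NIfTI with the units recorded in the header
description field and a JSON sidecar carrying metric name, units, and any
processing options; the units conventions are b in s/mm^2, D/MD in mm^2/s,
W/MK/FA dimensionless, CBF in mL/100 g/min.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "write_map", "read_sidecar",
           "METRIC_UNITS"]

METRIC_UNITS = {
    "MK": "dimensionless",
    "FA": "dimensionless",
    "MD": "mm^2/s",
    "CBF": "mL/100g/min",
}


def _affine(voxel_dims) -> np.ndarray:
    aff = np.diag(list(voxel_dims) + [1.0])
    return aff


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_volume(data: np.ndarray, path: str | Path,
                 voxel_dims=(1.0, 1.0, 1.0),
                 affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    if affine is None:
        affine = _affine(voxel_dims)
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))
    return path


def write_map(data: np.ndarray, metric: str, path: str | Path,
              voxel_dims=(1.0, 1.0, 1.0), sidecar: dict | None = None) -> Path:
    """Write a scalar parameter map plus its JSON sidecar."""
    path = Path(path)
    units = METRIC_UNITS.get(metric, "arbitrary")
    affine = _affine(voxel_dims)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header["descrip"] = f"{metric} [{units}]".encode()[:79]
    nib.save(img, str(path))
    meta = {"metric": metric, "units": units, "missing_value": "NaN"}
    if sidecar:
        meta.update(sidecar)
    sidecar_path = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar_path = Path(str(sidecar_path) + ".json")
    sidecar_path.write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_sidecar(map_path: str | Path) -> dict:
    p = Path(map_path)
    base = Path(str(p.with_suffix("").with_suffix("")) + ".json")
    return json.loads(base.read_text())
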