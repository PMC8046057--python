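"""Volume, mask, and sidecar I/O.

Volumes travel as multi-page TIFF stacks or NIfTI files (chosen by
extension); masks as 8-bit label images; calibration curves, landmarks and
phantom truth summaries as JSON sidecars.  Array axis order is (z, y, x)
with z the axial (tooth) axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import nibabel as nib
import tifffile

from .calibration import CalibratedVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_json",
    "read_json",
]

_NII = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NII)


def read_volume(path, voxel_size_um: float | None = None) -> CalibratedVolume:
    """Read a TIFF stack or NIfTI volume.

    For NIfTI the voxel size is taken from the header (mm → μm) unless
    overridden; TIFF requires ``voxel_size_um``.
    """
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if voxel_size_um is None:
            voxel_size_um = float(img.header.get_zooms()[0]) * 1000.0
    else:
        data = tifffile.imread(str(path)).astype(np.float32)
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required for TIFF input")
    return CalibratedVolume(data, voxel_size_um, provenance={"source": str(path)})


def write_volume(path, vol: CalibratedVolume | np.ndarray,
                 voxel_size_um: float | None = None) -> None:
    path = Path(path)
    if isinstance(vol, CalibratedVolume):
        data, vs = vol.data, vol.voxel_size_um
    else:
        data, vs = np.asarray(vol), voxel_size_um
        if vs is None:
            raise ValueError("voxel_size_um is required for a bare array")
    if _is_nifti(path):
        mm = vs / 1000.0
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.diag([mm] * 3 + [1.0]))
        nib.save(img, str(path))
    else:
        tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32),
                         photometric="minisblack")


def write_mask(path, mask: np.ndarray, voxel_size_um: float | None = None) -> None:
    """Write a boolean or label mask as 8-bit TIFF/NIfTI."""
    arr = np.asarray(mask)
    arr = arr.astype(np.uint8)
    path = Path(path)
    if _is_nifti(path):
        mm = (voxel_size_um or 1000.0) / 1000.0
        nib.save(nib.Nifti1Image(arr, np.diag([mm] * 3 + [1.0])), str(path))
    else:
        tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if _is_nifti(path):
        return np.asarray(nib.load(str(path)).dataobj).astype(np.uint8)
    return tifffile.imread(str(path)).astype(np.uint8)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
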