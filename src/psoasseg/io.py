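"""Readers and writers for the imaging formats the pipeline touches.

NIfTI-1 (``.nii`` / ``.nii.gz``) is the canonical interchange format for
both volumes and masks; a DICOM series directory is accepted read-only as
input sugar. Masks are stored as unsigned 8-bit {0, 1}; any nonzero value
on read maps to true, the common dialect across segmentation tools.

NIfTI stores arrays fastest-varying-first ``(x, y, z)``; the package's
internal order is ``(z, y, x)``, so arrays are transposed at the boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .volume import BinaryMask, ImageVolume, MaskLabel

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0]).astype(np.float64)
    aff[:3, 3] = origin
    return aff


def _load_nifti(path: Path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise IOError(
            f"{path}: voxel spacing missing or non-positive in header; "
            "refusing to assume isotropic 1 mm"
        )
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D image, got shape {data.shape}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    # (x, y, z) -> (z, y, x)
    return data.T, tuple(float(z) for z in zooms), origin


def _read_dicom_series(path: Path) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise IOError(f"no readable DICOM slices in {path}")
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    except AttributeError:
        slices.sort(key=lambda ds: int(ds.InstanceNumber))
    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise IOError(f"{path}: DICOM series lacks PixelSpacing; cannot assume 1 mm")
    sy, sx = (float(v) for v in first.PixelSpacing)  # DICOM: row spacing, col spacing
    if len(slices) > 1 and hasattr(first, "ImagePositionPatient"):
        sz = abs(
            float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])
        )
    else:
        sz = float(getattr(first, "SliceThickness", 0) or 0)
    if sz <= 0:
        raise IOError(f"{path}: cannot determine slice spacing from DICOM metadata")
    slope = float(getattr(first, "RescaleSlope", 1) or 1)
    intercept = float(getattr(first, "RescaleIntercept", 0) or 0)
    vox = np.stack([ds.pixel_array.astype(np.float32) for ds in slices], axis=0)
    vox = vox * slope + intercept
    origin = tuple(float(v) for v in getattr(first, "ImagePositionPatient", (0, 0, 0)))
    return ImageVolume(
        voxels=vox,
        spacing=(sx, sy, sz),
        origin=origin,
        case_id=str(getattr(first, "SeriesInstanceUID", path.name)),
    )


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Spacing comes from the file header; HU values are returned unmodified
    (DICOM rescale slope/intercept applied). Missing spacing metadata is an
    error — 1 mm is never silently assumed.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    data, spacing, origin = _load_nifti(path)
    return ImageVolume(
        voxels=np.asarray(data, dtype=np.float32),
        spacing=spacing,
        origin=origin,
        case_id=path.name.split(".")[0],
    )


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI, float32, with spacing/origin in the header."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(volume.voxels, dtype=np.float32).T,  # (z,y,x) -> (x,y,z)
        _affine(volume.spacing, volume.origin),
    )
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_mask(path: str | os.PathLike, label: MaskLabel = MaskLabel.BILATERAL) -> BinaryMask:
    """Read a binary mask from NIfTI; any nonzero voxel maps to true."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    data, spacing, origin = _load_nifti(path)
    return BinaryMask(
        voxels=data != 0,
        spacing=spacing,
        origin=origin,
        case_id=path.name.split(".")[0],
        label=label,
    )


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as NIfTI uint8 {0, 1}; round trip preserves every voxel."""
    path = Path(path)
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8).T,
        _affine(mask.spacing, mask.origin),
    )
    img.header.set_zooms(mask.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
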