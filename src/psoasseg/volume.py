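"""In-memory containers for CT volumes and binary segmentation masks.

Axis convention, shared by every module in the package: arrays are indexed
``(z, y, x)`` (slice-major, 0-based), while spacing and origin tuples are
given in world order ``(sx, sy, sz)`` / ``(ox, oy, oz)`` in millimetres, the
order NIfTI headers use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = ["ImageVolume", "BinaryMask", "MaskLabel", "merge_lr"]

#: Minimum number of slices: the 2.5D sampler needs a slice above and below.
MIN_SLICES = 3


class MaskLabel(str, Enum):
    LEFT_PSOAS = "left_psoas"
    RIGHT_PSOAS = "right_psoas"
    BILATERAL = "bilateral"


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive numbers, got {spacing!r}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D grid of CT intensities in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensities in HU, slice-major.
    spacing : (sx, sy, sz)
        Voxel spacing in mm, world (x, y, z) order.
    origin : (ox, oy, oz)
        Physical position of voxel (0, 0, 0) in mm.
    case_id : str
        Opaque identifier of the exam.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D voxel grid, got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < MIN_SLICES:
            raise ValueError(
                f"volume has {self.voxels.shape[0]} slices; at least {MIN_SLICES} "
                "are required (2.5D stacking needs both neighbours)"
            )
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class BinaryMask:
    """A boolean grid aligned to an :class:`ImageVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""
    label: MaskLabel = MaskLabel.BILATERAL

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask grid, got ndim={self.voxels.ndim}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.label = MaskLabel(self.label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_voxels(self, voxels: np.ndarray, label: MaskLabel | None = None) -> "BinaryMask":
        """A copy of this mask carrying new voxel data on the same grid."""
        return replace(self, voxels=voxels, label=label or self.label)

    def check_same_grid(self, other: "BinaryMask | ImageVolume") -> None:
        if self.shape != other.shape:
            raise ValueError(f"grid shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")


def merge_lr(left: BinaryMask, right: BinaryMask) -> BinaryMask:
    """Merge left and right single-muscle masks into one bilateral mask.

    Voxel-wise OR; the reported psoas muscle volume is bilateral.
    """
    left.check_same_grid(right)
    return BinaryMask(
        voxels=left.voxels | right.voxels,
        spacing=left.spacing,
        origin=left.origin,
        case_id=left.case_id,
        label=MaskLabel.BILATERAL,
    )
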