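"""Seeded synthetic abdominal-CT-like phantom cohort.

Each case is a fat-attenuation body ellipse with a bone column and two
muscle-attenuation tubes flanking it — a deliberately simple stand-in for
the paraspinal psoas muscles. The tubes taper toward the cranial/caudal
ends and never reach the first or last slices, mirroring how the muscle
sits inside an abdominal exam. Inter-case variability comes from a
per-case volume scale factor, centre jitter, and a smooth random
displacement field applied identically to image and ground-truth mask;
Gaussian HU noise is added to the image only, so the mask remains the
exact deformed tube support.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import write_mask, write_volume
from .volume import BinaryMask, ImageVolume, MaskLabel

__all__ = [
    "PhantomParams",
    "generate_case",
    "generate_cohort",
    "write_cohort",
    "analytic_tube_volume_cm3",
]


@dataclass
class PhantomParams:
    """Tunable description of the phantom cohort.

    Defaults are the desk scale: a 64x64x24 grid at (2, 2, 5) mm keeps the
    5 mm slice thickness of a routine abdominal protocol while staying small
    enough for end-to-end experiments on one CPU.
    """

    shape: tuple[int, int, int] = (24, 64, 64)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)  # (sx, sy, sz) mm
    muscle_hu: float = 55.0
    muscle_hu_std: float = 6.0  # per-case jitter of the muscle mean
    fat_hu: float = -100.0
    bone_hu: float = 400.0
    air_hu: float = -1000.0
    noise_std: float = 10.0  # additive Gaussian HU noise, image only
    tube_radius_mm: float = 13.0
    taper_exponent: float = 0.35  # r(t) ∝ (4 t (1-t))**taper_exponent
    tube_extent: float = 0.85  # fraction of slices the tubes span
    deform_amplitude_mm: float = 3.0
    deform_smoothness_mm: float = 24.0
    volume_scale_range: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube_radius_mm must be > 0")
        lo, hi = self.volume_scale_range
        if not (0 < lo <= hi):
            raise ValueError("volume_scale_range must satisfy 0 < min <= max")
        nz, ny, nx = self.shape
        sx, sy, _ = self.spacing
        if self.tube_radius_mm * np.sqrt(hi) > 0.2 * min(nx * sx, ny * sy):
            raise ValueError(
                "tube radius too large for the grid; tubes would not fit "
                "inside the body ellipse"
            )
        if self.tube_radius_mm < max(sx, sy):
            raise ValueError("tube radius below in-plane voxel size; grid too coarse")


def _radius_profile(params: PhantomParams, scale: float) -> np.ndarray:
    """Per-slice tube radius in mm; zero outside the tube extent."""
    nz = params.shape[0]
    z = np.arange(nz)
    half_span = params.tube_extent * nz / 2.0
    t = (z - (nz - 1) / 2.0) / (2.0 * half_span) + 0.5  # 0..1 across the extent
    r = np.zeros(nz)
    inside = (t > 0) & (t < 1)
    r[inside] = (4.0 * t[inside] * (1.0 - t[inside])) ** params.taper_exponent
    return params.tube_radius_mm * np.sqrt(scale) * r


def analytic_tube_volume_cm3(params: PhantomParams, scale: float = 1.0) -> float:
    """Closed-form bilateral tube volume: sum over slices of 2 * pi r(z)^2 * sz."""
    r = _radius_profile(params, scale)
    sz = params.spacing[2]
    return float((2.0 * np.pi * (r**2) * sz).sum() / 1000.0)


def _smooth_displacement(
    rng: np.random.Generator, params: PhantomParams
) -> list[np.ndarray]:
    """One shared displacement field (voxel units per axis), zero-mean, smooth."""
    nz, ny, nx = params.shape
    sx, sy, sz = params.spacing
    sigmas = (
        params.deform_smoothness_mm / sz,
        params.deform_smoothness_mm / sy,
        params.deform_smoothness_mm / sx,
    )
    spac = (sz, sy, sx)
    fields = []
    for ax in range(3):
        noise = rng.standard_normal((nz, ny, nx))
        smooth = ndimage.gaussian_filter(noise, sigma=sigmas)
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth *= params.deform_amplitude_mm / (peak * spac[ax])
        fields.append(smooth)
    return fields


def generate_case(params: PhantomParams, seed: int) -> tuple[ImageVolume, BinaryMask]:
    """Generate one phantom exam and its exact bilateral ground-truth mask.

    Deterministic in ``(params, seed)``.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = params.shape
    sx, sy, sz = params.spacing

    scale = rng.uniform(*params.volume_scale_range)
    muscle_hu = params.muscle_hu + rng.normal(0.0, params.muscle_hu_std)
    # small anatomical jitter of tube positions, in mm
    jitter = rng.normal(0.0, 1.5, size=4)

    yy, xx = np.meshgrid(
        (np.arange(ny) - (ny - 1) / 2.0) * sy,
        (np.arange(nx) - (nx - 1) / 2.0) * sx,
        indexing="ij",
    )
    body_a = 0.48 * nx * sx  # lateral semi-axis, mm
    body_b = 0.46 * ny * sy  # antero-posterior semi-axis, mm
    body = (xx / body_a) ** 2 + (yy / body_b) ** 2 <= 1.0

    image2d_base = np.where(body, params.fat_hu, params.air_hu)

    bone_r = 9.0  # mm
    bone_y = 0.30 * ny * sy  # posterior of centre
    bone = (xx**2 + (yy - bone_y) ** 2) <= bone_r**2

    radii = _radius_profile(params, scale)
    tube_y = 0.18 * ny * sy
    tube_dx = 0.20 * nx * sx
    centres = [
        (-tube_dx + jitter[0], tube_y + jitter[1]),
        (tube_dx + jitter[2], tube_y + jitter[3]),
    ]

    image = np.empty((nz, ny, nx), dtype=np.float32)
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for z in range(nz):
        sl = image2d_base.copy()
        sl[bone] = params.bone_hu
        if radii[z] > 0:
            for cx, cy in centres:
                tube = ((xx - cx) ** 2 + (yy - cy) ** 2) <= radii[z] ** 2
                sl[tube] = muscle_hu
                mask[z] |= tube
        image[z] = sl

    if params.deform_amplitude_mm > 0:
        disp = _smooth_displacement(rng, params)
        idx = np.indices((nz, ny, nx), dtype=np.float64)
        coords = [idx[ax] + disp[ax] for ax in range(3)]
        image = ndimage.map_coordinates(image, coords, order=1, mode="nearest").astype(
            np.float32
        )
        mask = ndimage.map_coordinates(
            mask.astype(np.uint8), coords, order=0, mode="nearest"
        ).astype(bool)

    if params.noise_std > 0:
        image = image + rng.normal(0.0, params.noise_std, size=image.shape).astype(
            np.float32
        )

    case_id = f"case_{seed & 0x7FFFFFFF:010d}"
    vol = ImageVolume(image, params.spacing, case_id=case_id)
    gt = BinaryMask(mask, params.spacing, case_id=case_id, label=MaskLabel.BILATERAL)
    return vol, gt


def generate_cohort(
    n: int, params: PhantomParams | None = None, master_seed: int = 0
) -> list[tuple[ImageVolume, BinaryMask]]:
    """Generate ``n`` phantom cases with per-case seeds derived from the master seed.

    Per-case seeds come from a counter-based ``SeedSequence`` spawn, so the
    cohort is reproducible and independent of generation order.
    """
    if n < 2:
        raise ValueError("a cohort needs n >= 2 cases (cross-validation impossible)")
    params = params or PhantomParams()
    seeds = np.random.SeedSequence(master_seed).generate_state(n) & 0x7FFFFFFF
    cases = []
    for i, seed in enumerate(seeds):
        vol, gt = generate_case(params, int(seed))
        vol.case_id = gt.case_id = f"case_{i:03d}"
        cases.append((vol, gt))
    return cases


def write_cohort(
    cases: list[tuple[ImageVolume, BinaryMask]], out_dir: str | Path
) -> Path:
    """Write a cohort as NIfTI pairs plus a ``manifest.csv`` of true volumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "true_volume_cm3"])
        for vol, gt in cases:
            write_volume(vol, out_dir / f"{vol.case_id}_img.nii.gz")
            write_mask(gt, out_dir / f"{vol.case_id}_mask.nii.gz")
            vol_cm3 = gt.count * gt.voxel_volume_mm3 / 1000.0
            writer.writerow([vol.case_id, f"{vol_cm3:.4f}"])
    return manifest
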