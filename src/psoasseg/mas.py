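"""Multi-atlas segmentation with energy-ranked atlas selection.

Each labelled reference exam (atlas) is registered to the target in two
stages: a multi-resolution affine stage minimizing mean squared error on a
coarse-to-fine pyramid (each level initialized from the previous one),
followed by a B-spline free-form deformation maximizing mutual
information. The atlas mask is propagated through the composed transform
with nearest-neighbour interpolation. Registrations are ranked by the
final minimized energy — the finest-level metric value, which for the
Mattes formulation is negative mutual information, so lower is uniformly
better — the five best are kept, and their propagated masks are fused by
strict majority vote (a voxel is muscle iff found in > 50% of the masks).

The registration backend is SimpleITK; everything above the two
``Execute`` calls (staging, ranking, voting, failure handling) is this
package's contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from sklearn.base import BaseEstimator

from .volume import BinaryMask, ImageVolume, MaskLabel

__all__ = [
    "Atlas",
    "AffineStageConfig",
    "BSplineStageConfig",
    "RegistrationOutcome",
    "RegistrationFailure",
    "register_pair",
    "warp_mask",
    "rank_and_select",
    "majority_vote",
    "mas_segment",
    "MultiAtlasSegmenter",
]


@dataclass
class Atlas:
    """A labelled reference exam used as registration source."""

    image: ImageVolume
    mask: BinaryMask
    case_id: str = ""

    def __post_init__(self) -> None:
        self.mask.check_same_grid(self.image)
        if not self.case_id:
            self.case_id = self.image.case_id


@dataclass
class AffineStageConfig:
    """Multi-resolution affine stage: mean-squared-error metric, gradient descent.

    ``pyramid`` lists downscaling factors coarse to fine; levels whose
    coarsest grid would drop below 4 voxels on any axis are pruned
    automatically per target.
    """

    pyramid: tuple[int, ...] = (8, 4, 2, 1)
    iterations: int = 40
    learning_rate: float = 2.0
    min_step: float = 1e-4
    relaxation: float = 0.6

    def __post_init__(self) -> None:
        p = tuple(self.pyramid)
        if p[-1] != 1 or any(a <= b for a, b in zip(p, p[1:])):
            raise ValueError("pyramid factors must be strictly decreasing and end at 1")
        self.pyramid = p


@dataclass
class BSplineStageConfig:
    """B-spline stage: Mattes mutual information, adaptive gradient descent."""

    grid_spacing_mm: float = 32.0
    mi_bins: int = 32
    iterations: int = 25
    sampling_fraction: float = 0.1
    max_step_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.grid_spacing_mm <= 0 or not (0 < self.sampling_fraction <= 1):
            raise ValueError("invalid B-spline stage configuration")


@dataclass
class RegistrationOutcome:
    """Result of one atlas-to-target registration."""

    atlas_case_id: str
    affine_transform: sitk.Transform
    bspline_transform: sitk.Transform
    final_energy: float  # finest-level metric value; lower = better
    affine_energy: float
    warped_mask: BinaryMask = field(repr=False, default=None)


class RegistrationFailure(RuntimeError):
    """Optimizer divergence or non-finite metric for one atlas."""


def _to_sitk(volume: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels, dtype=np.float32))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    return img


def _mask_to_sitk(mask: BinaryMask) -> sitk.Image:
    img = sitk.GetImageFromArray(mask.voxels.astype(np.uint8))
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    return img


def _prune_pyramid(factors: tuple[int, ...], shape: tuple[int, int, int]) -> list[int]:
    kept = [f for f in factors if min(shape) // f >= 4]
    return kept or [1]


def warp_mask(
    mask: BinaryMask, transform: sitk.Transform, reference: ImageVolume
) -> BinaryMask:
    """Propagate an atlas mask onto a target grid (nearest-neighbour)."""
    ref = _to_sitk(reference)
    warped = sitk.Resample(
        _mask_to_sitk(mask), ref, transform, sitk.sitkNearestNeighbor, 0.0,
        sitk.sitkUInt8,
    )
    return BinaryMask(
        sitk.GetArrayFromImage(warped) != 0,
        reference.spacing,
        origin=reference.origin,
        case_id=reference.case_id,
        label=MaskLabel.BILATERAL,
    )


def register_pair(
    target: ImageVolume,
    atlas: Atlas,
    affine_cfg: AffineStageConfig | None = None,
    bspline_cfg: BSplineStageConfig | None = None,
    seed: int = 1,
) -> RegistrationOutcome:
    """Dual-stage registration of one atlas onto the target.

    Raises :class:`RegistrationFailure` when the optimizer produces a
    non-finite metric; callers treat that atlas as unusable and move on.
    """
    affine_cfg = affine_cfg or AffineStageConfig()
    bspline_cfg = bspline_cfg or BSplineStageConfig()
    if bspline_cfg.grid_spacing_mm <= max(target.spacing):
        raise ValueError("B-spline control-point spacing must exceed voxel spacing")
    fixed = _to_sitk(target)
    moving = _to_sitk(atlas.image)

    levels = _prune_pyramid(affine_cfg.pyramid, target.shape)
    try:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetShrinkFactorsPerLevel(levels)
        reg.SetSmoothingSigmasPerLevel([f / 2.0 for f in levels])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=affine_cfg.learning_rate,
            minStep=affine_cfg.min_step,
            numberOfIterations=affine_cfg.iterations,
            relaxationFactor=affine_cfg.relaxation,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        initial = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.AffineTransform(3),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
        reg.SetInitialTransform(initial, inPlace=True)
        affine = reg.Execute(fixed, moving)
        affine_energy = reg.GetMetricValue()

        mesh = [
            max(1, int(round(sz * sp / bspline_cfg.grid_spacing_mm)))
            for sz, sp in zip(fixed.GetSize(), fixed.GetSpacing())
        ]
        bspline = sitk.BSplineTransformInitializer(fixed, mesh)
        reg2 = sitk.ImageRegistrationMethod()
        reg2.SetMetricAsMattesMutualInformation(bspline_cfg.mi_bins)
        reg2.SetMetricSamplingStrategy(reg2.RANDOM)
        reg2.SetMetricSamplingPercentage(
            bspline_cfg.sampling_fraction, int(seed) % (2**31 - 1) or 1
        )
        reg2.SetInterpolator(sitk.sitkLinear)
        reg2.SetOptimizerAsGradientDescent(
            learningRate=1.0,
            numberOfIterations=bspline_cfg.iterations,
            estimateLearningRate=reg2.Once,
            maximumStepSizeInPhysicalUnits=bspline_cfg.max_step_mm,
        )
        # B-spline parameters are homogeneous displacements: uniform scales;
        # physical-shift scale estimation over ~10^3 coefficients dominates
        # runtime without improving the fit at this problem size.
        reg2.SetMovingInitialTransform(affine)
        reg2.SetInitialTransform(bspline, inPlace=True)
        reg2.Execute(fixed, moving)
        final_energy = reg2.GetMetricValue()
    except RuntimeError as exc:
        raise RegistrationFailure(
            f"registration of atlas {atlas.case_id!r} failed: {exc}"
        ) from exc
    if not np.isfinite(final_energy) or not np.isfinite(affine_energy):
        raise RegistrationFailure(
            f"registration of atlas {atlas.case_id!r} produced a non-finite metric"
        )

    composite = sitk.CompositeTransform(3)
    composite.AddTransform(affine)
    composite.AddTransform(bspline)
    warped = warp_mask(atlas.mask, composite, target)
    return RegistrationOutcome(
        atlas_case_id=atlas.case_id,
        affine_transform=affine,
        bspline_transform=bspline,
        final_energy=float(final_energy),
        affine_energy=float(affine_energy),
        warped_mask=warped,
    )


def rank_and_select(
    outcomes: list[RegistrationOutcome], k: int = 5
) -> list[RegistrationOutcome]:
    """The ``k`` best registrations by minimized energy (ascending).

    Ties break deterministically on the atlas case id. Fewer than ``k``
    successful outcomes are all returned; none is an error.
    """
    if not outcomes:
        raise ValueError("no successful registrations")
    ranked = sorted(outcomes, key=lambda o: (o.final_energy, o.atlas_case_id))
    return ranked[: min(k, len(ranked))]


def majority_vote(masks: list[BinaryMask]) -> BinaryMask:
    """Strict-majority label fusion: a voxel is muscle iff votes > n/2.

    For five masks that means at least three votes; with an even count an
    exact half is excluded (the inequality is strict).
    """
    if not masks:
        raise ValueError("majority_vote needs at least one mask")
    first = masks[0]
    votes = np.zeros(first.shape, dtype=np.int32)
    for m in masks:
        first.check_same_grid(m)
        votes += m.voxels
    return first.with_voxels(votes > len(masks) / 2.0, label=MaskLabel.BILATERAL)


def mas_segment(
    target: ImageVolume,
    atlases: list[Atlas],
    affine_cfg: AffineStageConfig | None = None,
    bspline_cfg: BSplineStageConfig | None = None,
    k: int = 5,
    seed: int = 1,
) -> BinaryMask:
    """Register all atlases, keep the five lowest-energy fits, majority-vote."""
    outcomes, _ = _register_all(target, atlases, affine_cfg, bspline_cfg, seed)
    selected = rank_and_select(outcomes, k=k)
    return majority_vote([o.warped_mask for o in selected])


def _register_all(target, atlases, affine_cfg, bspline_cfg, seed):
    if not atlases:
        raise ValueError("need at least one atlas")
    outcomes, failures = [], []
    # fixed per-pair seed: ranking is invariant to atlas processing order
    for atlas in sorted(atlases, key=lambda a: a.case_id):
        try:
            outcomes.append(
                register_pair(target, atlas, affine_cfg, bspline_cfg, seed=seed)
            )
        except RegistrationFailure as exc:
            warnings.warn(str(exc), stacklevel=3)
            failures.append(atlas.case_id)
    return outcomes, failures


class MultiAtlasSegmenter(BaseEstimator):
    """sklearn-style multi-atlas segmenter.

    ``fit`` stores the training exams as the atlas pool; ``predict``
    registers every atlas to the query volume, selects the ``k`` best by
    minimized energy and fuses their propagated masks by strict majority
    vote. ``predict`` also records the per-atlas energies of the last
    query in ``last_outcomes_``.
    """

    def __init__(self, k: int = 5, pyramid: tuple[int, ...] = (8, 4, 2, 1),
                 affine_iterations: int = 40, grid_spacing_mm: float = 32.0,
                 mi_bins: int = 32, sampling_fraction: float = 0.1,
                 bspline_iterations: int = 25, seed: int = 1):
        self.k = k
        self.pyramid = pyramid
        self.affine_iterations = affine_iterations
        self.grid_spacing_mm = grid_spacing_mm
        self.mi_bins = mi_bins
        self.sampling_fraction = sampling_fraction
        self.bspline_iterations = bspline_iterations
        self.seed = seed

    def _configs(self) -> tuple[AffineStageConfig, BSplineStageConfig]:
        return (
            AffineStageConfig(pyramid=tuple(self.pyramid),
                              iterations=self.affine_iterations),
            BSplineStageConfig(grid_spacing_mm=self.grid_spacing_mm,
                               mi_bins=self.mi_bins,
                               sampling_fraction=self.sampling_fraction,
                               iterations=self.bspline_iterations),
        )

    def fit(self, volumes, masks):
        atlases = [Atlas(v, m) for v, m in zip(volumes, masks, strict=True)]
        if not atlases:
            raise ValueError("need at least one atlas")
        self.atlases_ = atlases
        return self

    def predict(self, volume: ImageVolume) -> BinaryMask:
        affine_cfg, bspline_cfg = self._configs()
        outcomes, failures = _register_all(
            volume, self.atlases_, affine_cfg, bspline_cfg, self.seed
        )
        selected = rank_and_select(outcomes, k=self.k)
        self.last_outcomes_ = outcomes
        self.last_selected_ = [o.atlas_case_id for o in selected]
        self.last_failures_ = failures
        return majority_vote([o.warped_mask for o in selected])
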