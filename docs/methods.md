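# Methods

This note documents the models, parameters and design decisions behind
`psoasseg`, in the spirit of a methods appendix: what is computed, what
was genuinely open and how it was decided, and what the synthetic
evaluation does and does not show.

## Data model

Volumes and masks are 3D grids indexed `(z, y, x)` (slice-major) with
spacing/origin in world `(x, y, z)` order, millimetres. NIfTI-1 is the
interchange format; masks are written as uint8 {0, 1} and any nonzero
voxel maps to true on read, the dialect most segmentation tools accept. A
DICOM series directory is accepted read-only (slope/intercept applied,
slice spacing from positions). Missing spacing metadata is always an
error — 1 mm is never assumed. Volumes need at least three slices because
the 2.5D sampler requires both neighbours of an interior slice.

## Phantom cohort

Each synthetic exam is a fat-attenuation (−100 HU) body ellipse in air,
a bone column (+400 HU), and two muscle-attenuation (≈55 HU) tubes
flanking it — a minimal stand-in for the paraspinal psoas muscles.
Defaults, chosen once as desk-scale study conditions:

| parameter | default | why |
|---|---|---|
| grid, spacing | 64×64×24, (2, 2, 5) mm | keeps the 5 mm slice thickness of routine abdominal CT while allowing minutes-scale end-to-end runs on one CPU |
| tube radius | 13 mm, tapering as (4t(1−t))^0.35 over the central 85% of slices | psoas-like calibre; the muscle never reaches the first/last slices, matching the premise that edge slices carry no muscle |
| volume scale | per-case uniform in (0.8, 1.25) | inter-patient size variability; implies a cohort volume CV of ≈13% |
| deformation | smoothed-white-noise displacement field, 3 mm amplitude, 24 mm smoothness | per-case shape variability; backward warping, linear for the image and nearest-neighbour for the mask, one shared field for both |
| noise | additive Gaussian, σ = 10 HU, image only | the mask stays the exact deformed tube support |

Per-case seeds derive from the master seed via a counter-based
`SeedSequence`, so cohorts are reproducible independent of generation
order. The phantom does **not** model organs, contrast phases, HU
calibration error, streak artefacts, or anatomical variants; passing
tests on it demonstrates the pipeline's mechanics and relative behaviour
of the three routes, not clinical-grade accuracy.

## Multi-atlas segmentation

Registration runs through SimpleITK. Stage 1 is affine with a
mean-squared-error metric on a shrink pyramid 8/4/2/1 (levels whose
coarsest grid would fall below 4 voxels on an axis are pruned per
target), regular-step gradient descent (40 iterations/level, initial
step 2.0, relaxation 0.6), geometry-centred initialization. Stage 2 is a
B-spline free-form deformation (control-point spacing 32 mm) maximizing
Mattes mutual information (32 bins, 10% random sampling with a fixed
seed), gradient descent with a one-time estimated learning rate capped
at 2 mm per step, 25 iterations. Uniform parameter scales are used for
the B-spline stage: its parameters are homogeneous displacements, and
physical-shift scale estimation over ~10³ coefficients dominates runtime
without improving the fit at this problem size.

The ranking energy is the finest-level metric value of stage 2. Mattes
MI is implemented as negative mutual information (it is minimized), so a
single lower-is-better scale ranks all atlases; the five best propagate
their masks, fused by strict majority (> n/2, so ≥ 3 of 5; an exact half
with even n is excluded). Ties in energy break on the atlas case id.
A registration producing a non-finite metric is flagged, logged and
excluded from ranking rather than aborting the segmentation.

Iteration counts and step sizes are desk-scale defaults chosen for the
phantom cohort and are config-exposed; no published parameter set exists
for this pipeline stage.

## 2.5D adversarial segmenter

The generator is an encoder–decoder with skip connections: stride-2 4×4
convolutions halve resolution down to a 4×4 bottleneck (4 levels at
64 px input), and the decoder mirrors with nearest-neighbour upsampling +
3×3 convolution on concatenated skips, ending in a sigmoid. The
discriminator is a three-layer patch classifier on the concatenated
image+mask channels. Channel widths start at `base_channels` and double
up to 4×. All layers are numpy with hand-written backprop (`psoasseg.nn`),
verified against finite differences.

Numerical choices that mattered:

- **He-scaled initialization and instance normalization.** With a rare
  foreground (~5% of pixels) the L1 term's sign gradient plus a sigmoid
  output is prone to total collapse: the majority class drives every
  logit down, the sigmoid saturates, and confidently-wrong foreground
  pixels receive vanishing gradients. Per-channel instance normalization
  keeps pre-activations centred and eliminates the collapse; He-scaled
  weights keep activations O(1) through depth without normalization at
  the input layer (raw intensities are informative there).
- **Intensity windowing.** Inputs are clipped to a soft-tissue window
  [−200, 300] HU and scaled to [−1, 1]; muscle/fat contrast drives the
  task.
- **Edge slices.** Only interior slices (2..n−1, 1-based) are trained
  on; at inference the two edge slices are predicted with
  replicated-neighbour padding so every slice of the volume is covered.
  On realistic anatomy the muscle does not reach those slices, so the
  effect is nil, but the contract defines every voxel.
- **Binarization** at 0.5 on the sigmoid output; labels are resized with
  nearest-neighbour in both directions so they stay binary.
- **Adversarial form.** The original log-form generator loss
  (minimizing log(1 − D)) is the default; a non-saturating variant is
  config-switchable because the log form can saturate at small scale.
  The discriminator trains on the standard real-up/fake-down cross-
  entropy, half-weighted per side.

Reference configuration: 256 px inputs, 50 epochs, Adam(lr 2×10⁻⁴,
β₁ 0.5), batch 8, L1 weight 10. Desk configuration (`GanConfig.desk()`,
also the estimator defaults): 64 px, 12 epochs, batch 4, base 8
channels, lr 10⁻³ — the step size is scaled up as the iteration budget
scales down (a desk run sees ~500 updates versus ~24 000 at reference
scale). Determinism is promised per device only: floating-point
reduction order varies across BLAS builds.

## Fusion

The combined mask is `dilate(MAS, 2 px) AND GAN`. Dilation is in-plane
(per-slice) with a 4-connected cross applied twice, giving the 13-voxel
city-block diamond around an isolated voxel: the operator is defined in
pixels, and with 5 mm slices against 2 mm in-plane voxels a 3D ball
would be anisotropically wrong. Both the 3D variant and the structuring
element are config-exposed; whether the original operator was 2D or 3D
is undocumented, so the 2D default is this package's choice.

## Evaluation harness

- Volume: count × voxel volume / 1000, cm³.
- DSC: 2|A∩B|/(|A|+|B|); two empty masks score 1.0 (perfect agreement on
  absence — a convention, stated because degenerate inputs must behave).
- Spearman ρ: Pearson correlation of mid-ranks; constant input is
  flagged (warning + NaN) rather than silently 0.
- Wilcoxon signed-rank (paired, two-sided): zeros dropped; exact null
  distribution via dynamic programming over doubled mid-ranks for
  n ≤ 25 (equivalent to enumerating all 2ⁿ sign assignments, ties
  included), tie-corrected normal approximation above. All-zero
  differences degenerate to p = 1 with a warning.
- Volume-error statistics report the signed cohort-mean error in %, the
  mean squared difference, and its root — both of the latter, because a
  squared volume is not a volume and labels should be unambiguous.
- Median DSC confidence intervals: seeded nonparametric bootstrap
  (10 000 resamples, percentile method).
- Folds: seeded shuffle then split into k chunks (sizes differing by at
  most one, larger first); every case tests exactly once, and per fold
  both the atlas pool and the network are built from training cases
  only.

## Known limitations

- The phantom's two-tissue contrast makes the slice network's task far
  easier than clinical CT; absolute Dice values on phantoms
  (≈0.87–0.95) say nothing about clinical performance and are not
  comparable to values reported on patient data.
- The numpy network is CPU-bound and desk-scale; the reference
  configuration (256 px, 50 epochs) is supported but slow.
- Per-side (left/right) masks and metrics are representable
  (`MaskLabel`, `merge_lr`) but the harness evaluates the bilateral
  muscle, which is the reported quantity.
- Registration quality depends on the desk-scale iteration budgets;
  harder targets may need the config-exposed budgets raised.
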