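# psoasseg

Automated volumetry of the psoas major muscle (PMM) in abdominal CT.

The PMM volume (PMMV) is an opportunistic imaging biomarker: abdominal CT
exams acquired for any indication depict the muscle completely, and its
volume tracks overall skeletal muscle mass, making it a practical proxy in
sarcopenia assessment. Manual 3D segmentation is accurate but slow, so
this package implements and compares three automated routes plus the full
evaluation protocol, exercised end-to-end on a built-in synthetic CT
phantom cohort (the package is aimed at method developers; the phantom
stands in for clinical data, which such cohorts rarely allow to be
shared).

## Methods

**Multi-atlas segmentation (MAS).** Every labelled training exam (atlas)
is registered to the target volume in two stages: a multi-resolution
affine stage (mean squared error, gradient descent, pyramid downscaled by
8/4/2/1 with each level initialized from the previous one) followed by a
B-spline free-form deformation maximizing mutual information. Atlas masks
are propagated with nearest-neighbour interpolation, registrations are
ranked by the minimized energy (the finest-level metric value), and the
five best masks are fused by strict majority vote: a voxel is muscle iff
it appears in more than n/2 of the propagated masks.

**2.5D adversarial network (GAN).** A 2D encoder–decoder generator G maps
a slice to a binary mask; each input stacks the active slice with its
neighbours above and below (three channels) to inject through-plane
context. A patch discriminator D judges (image, mask) pairs. With x the
input and y the reference mask,

    L_GAN(G, D) = E_y[log D(x, y)] + E_x[log(1 − D(x, G(x)))]
    L_L1(G)     = E_{x,y}[ ‖y − G(x)‖₁ ]

and the generator objective is `1.0·L_GAN + 10.0·L_L1`. Training slices
run from 2 to n−1 (the edge slices lack one neighbour); optimization is
Adam with momentum term β₁ = 0.5. The network stack is implemented in
numpy with explicit backpropagation (see `psoasseg.nn`).

**Combined approach (COM).** The MAS mask is dilated by 2 pixels in-plane
and intersected voxel-wise (AND) with the network mask: the atlas route
contributes robust global localization, the network route precise
boundaries, and the intersection suppresses the network's occasional
distant false positives.

**Evaluation.** PMMV = voxel count × voxel volume (cm³); overlap via the
Dice similarity coefficient (DSC); cohort agreement via Spearman's rank
correlation and the paired Wilcoxon signed-rank test (exact null up to
n = 25); five-fold cross-validation with patient-level 80/20 splits so
every case is tested exactly once by models that never saw it.

## Worked example

```python
from psoasseg import (PhantomParams, generate_cohort, run_experiment)

cohort = generate_cohort(10, PhantomParams(), master_seed=1)
table, summary = run_experiment(cohort, k=5, seed=1)
for method, s in summary["methods"].items():
    print(f"{method}: median DSC {s['median_dsc']:.3f} "
          f"[{s['dsc_ci95'][0]:.3f}, {s['dsc_ci95'][1]:.3f}], "
          f"volume error {s['mean_signed_pct']:+.1f}%")
```

prints (one CPU, ~7 minutes):

```
GAN: median DSC 0.947 [0.944, 0.955], volume error -2.1%
MAS: median DSC 0.875 [0.828, 0.892], volume error +4.1%
COM: median DSC 0.947 [0.941, 0.955], volume error -2.4%
```

Each line is one segmentation route evaluated on the ten held-out phantom
cases across the five folds: the median Dice overlap with ground truth
(bootstrap 95% CI), and the signed error of the cohort-mean predicted
volume against the cohort-mean true volume. The combined route matches or
beats both components on overlap and is markedly better than the
multi-atlas route at volumetry — the qualitative behaviour the method is
designed for.

The same estimators compose in the scikit-learn style:

```python
from psoasseg import MultiAtlasSegmenter, AdversarialSliceSegmenter, CombinedSegmenter

seg = CombinedSegmenter(mas=MultiAtlasSegmenter(k=5),
                        gan=AdversarialSliceSegmenter(epochs=12, seed=0))
seg.fit(train_volumes, train_masks)
mask = seg.predict(test_volume)   # BinaryMask on the test volume's grid
```

A `psoasseg` command exposes the same pipeline from the shell
(`phantom`, `mas`, `gan train`, `gan predict`, `fuse`, `evaluate`,
`run-all`); every run echoes its effective configuration beside its
outputs.

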