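"""Volumetry, overlap metrics, cohort statistics and the cross-validation harness.

The muscle volume (PMMV) of a mask is voxel count times voxel volume, in
cm^3. Segmentation overlap is the Dice similarity coefficient. Cohort-level
agreement between automated and manual volumes uses Spearman's rank
correlation and the paired Wilcoxon signed-rank test (the per-case scores
are paired but not Gaussian); the Wilcoxon null distribution is exact
(dynamic programming over signed midranks) up to n = 25 and a tie-corrected
normal approximation above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volume import BinaryMask

__all__ = [
    "EvalRecord",
    "FoldSplit",
    "compute_volume",
    "dsc",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "volume_error_stats",
    "bootstrap_median_ci",
    "make_folds",
    "run_experiment",
]


@dataclass
class EvalRecord:
    """Per-case, per-method metrics; ``dsc`` is None for the TRUTH rows."""

    case_id: str
    method: str  # one of GAN, MAS, COM, TRUTH
    volume_cm3: float
    dsc: float | None = None
    fold: int | None = None


@dataclass
class FoldSplit:
    """One cross-validation fold: a patient-level train/test partition."""

    index: int
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)


def compute_volume(mask: BinaryMask) -> float:
    """Mask volume in cm^3: voxel count x voxel volume (mm^3) / 1000."""
    return mask.count * mask.voxel_volume_mm3 / 1000.0


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); two empty masks agree (1.0)."""
    a.check_same_grid(b)
    na, nb = a.count, b.count
    if na + nb == 0:
        return 1.0
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def spearman_rho(xs, ys) -> float:
    """Spearman's rank correlation: Pearson correlation of mid-ranks."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if xs.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rx = stats.rankdata(xs)  # mid-ranks for ties
    ry = stats.rankdata(ys)
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_signed_rank_p(doubled_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Two-sided exact p via DP over the 2^n equiprobable sign assignments.

    Works on doubled mid-ranks so all sums are integers even with ties.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    cdf = np.cumsum(counts)
    p_le = cdf[w_plus_doubled]
    p_ge = counts[w_plus_doubled:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(xs, ys, exact_max_n: int = 25) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-sided p).

    Zero differences are dropped. The null distribution is exact for
    n <= ``exact_max_n`` remaining pairs and a tie-corrected normal
    approximation beyond. All differences zero degenerates to p = 1.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("inputs must be paired equal-length 1D sequences")
    d = xs - ys
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        doubled = np.rint(2 * ranks).astype(int)
        p = _exact_signed_rank_p(doubled, int(round(2 * w_plus)))
        return w_plus, p
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


def volume_error_stats(pred, truth) -> dict[str, float]:
    """Cohort volume agreement: mean signed error %, mean squared diff, RMSE.

    The signed percentage compares cohort means: (mean(pred) - mean(truth))
    / mean(truth) x 100. The squared difference is per-case, averaged; its
    root is reported alongside because a squared volume is not itself a
    volume.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("paired lists must have equal length")
    msd = float(np.mean((pred - truth) ** 2))
    return {
        "mean_signed_pct": float((pred.mean() - truth.mean()) / truth.mean() * 100.0),
        "mean_squared_diff": msd,
        "rmse": float(np.sqrt(msd)),
    }


def bootstrap_median_ci(
    values, n_boot: int = 10_000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Median with a seeded nonparametric bootstrap percentile CI."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    lo, hi = np.percentile(meds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(np.median(values)), float(lo), float(hi)


def make_folds(case_ids, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Patient-level k-fold partition: seeded shuffle, larger folds first.

    Every case tests in exactly one fold and trains in the others.
    """
    case_ids = list(case_ids)
    if len(case_ids) < k:
        raise ValueError(f"need at least k={k} cases, got {len(case_ids)}")
    rng = np.random.default_rng(seed)
    order = list(np.array(case_ids, dtype=object)[rng.permutation(len(case_ids))])
    chunks = np.array_split(order, k)  # sizes differ by at most one, larger first
    folds = []
    for i, chunk in enumerate(chunks):
        test = [str(c) for c in chunk]
        train = [c for c in case_ids if c not in test]
        folds.append(FoldSplit(index=i + 1, train_ids=train, test_ids=test))
    return folds


def _summarize(records: pd.DataFrame, seed: int, n_boot: int = 10_000) -> dict:
    truth = records[records.method == "TRUTH"].set_index("case_id").volume_cm3
    summary: dict = {"n_cases": int(truth.size), "methods": {}}
    for method in ["GAN", "MAS", "COM"]:
        rows = records[records.method == method].set_index("case_id")
        if rows.empty:
            continue
        pred = rows.volume_cm3.reindex(truth.index)
        med, lo, hi = bootstrap_median_ci(rows.dsc.to_numpy(), n_boot, seed)
        _, p_vol = wilcoxon_signed_rank(pred.to_numpy(), truth.to_numpy())
        entry = {
            "median_dsc": med,
            "dsc_ci95": [lo, hi],
            "spearman_rho": spearman_rho(pred.to_numpy(), truth.to_numpy()),
            "wilcoxon_p_volume": p_vol,
            **volume_error_stats(pred.to_numpy(), truth.to_numpy()),
        }
        summary["methods"][method] = entry
    return summary


def run_experiment(
    cohort,
    k: int = 5,
    seed: int = 0,
    mas_params: dict | None = None,
    gan_params: dict | None = None,
    radius_px: int = 2,
    n_boot: int = 10_000,
) -> tuple[pd.DataFrame, dict]:
    """Fivefold cross-validated comparison of GAN, MAS and COM on a cohort.

    ``cohort`` is a list of (ImageVolume, BinaryMask) pairs. Per fold, the
    multi-atlas pool and the adversarial network are built from the training
    cases only, then all three methods segment each held-out test case.
    Returns the per-case record table and a cohort summary (median DSC with
    bootstrap 95% CI, Spearman rho, Wilcoxon p and volume-error statistics
    per method).
    """
    from .fusion import combine
    from .gan import AdversarialSliceSegmenter
    from .mas import MultiAtlasSegmenter

    by_id = {vol.case_id: (vol, gt) for vol, gt in cohort}
    if len(by_id) != len(cohort):
        raise ValueError("case_ids must be unique")
    folds = make_folds(list(by_id), k=k, seed=seed)
    records: list[EvalRecord] = []
    for fold in folds:
        fold_seed = (seed * 1000 + fold.index) & 0x7FFFFFFF
        train_vols = [by_id[c][0] for c in fold.train_ids]
        train_masks = [by_id[c][1] for c in fold.train_ids]
        mas = MultiAtlasSegmenter(**(mas_params or {}), seed=fold_seed)
        gan = AdversarialSliceSegmenter(**(gan_params or {}), seed=fold_seed)
        mas.fit(train_vols, train_masks)
        gan.fit(train_vols, train_masks)
        for case_id in fold.test_ids:
            vol, gt = by_id[case_id]
            preds = {"MAS": mas.predict(vol), "GAN": gan.predict(vol)}
            preds["COM"] = combine(preds["MAS"], preds["GAN"], radius_px=radius_px)
            records.append(
                EvalRecord(case_id, "TRUTH", compute_volume(gt), None, fold.index)
            )
            for method, pred in preds.items():
                records.append(
                    EvalRecord(
                        case_id,
                        method,
                        compute_volume(pred),
                        dsc(pred, gt),
                        fold.index,
                    )
                )
    table = pd.DataFrame([r.__dict__ for r in records])
    summary = _summarize(table, seed=seed, n_boot=n_boot)
    return table, summary
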