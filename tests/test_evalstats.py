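"""Volumetry, overlap and cohort statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from psoasseg import (
    BinaryMask,
    compute_volume,
    dsc,
    make_folds,
    spearman_rho,
    volume_error_stats,
    wilcoxon_signed_rank,
)
from psoasseg.evalstats import bootstrap_median_ci


def _mask_from_count(count, shape=(10, 10, 10), spacing=(1, 1, 5), offset=0):
    vox = np.zeros(shape, bool)
    vox.flat[offset : offset + count] = True
    return BinaryMask(vox, spacing)


class TestDice:
    def test_identical_nonempty_is_one(self):
        m = _mask_from_count(42)
        assert dsc(m, m) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        assert dsc(_mask_from_count(10), _mask_from_count(10, offset=500)) == 0.0

    def test_formula_forced_case(self):
        # |A|=4, |B|=6, |A∩B|=3 -> 2*3/10 = 0.6
        a = _mask_from_count(4)
        b_vox = np.zeros((10, 10, 10), bool)
        b_vox.flat[1:4] = True  # 3 overlapping
        b_vox.flat[100:103] = True  # 3 elsewhere
        b = BinaryMask(b_vox, (1, 1, 5))
        assert dsc(a, b) == pytest.approx(0.6)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        a = BinaryMask(rng.random((5, 6, 6)) < 0.4, (1, 1, 1))
        b = BinaryMask(rng.random((5, 6, 6)) < 0.4, (1, 1, 1))
        assert dsc(a, b) == dsc(b, a)
        assert 0.0 <= dsc(a, b) <= 1.0

    def test_both_empty_agree(self):
        e = _mask_from_count(0)
        assert dsc(e, e) == 1.0


class TestVolume:
    def test_thousand_voxels_at_1x1x5(self):
        assert compute_volume(_mask_from_count(1000)) == pytest.approx(5.0)

    def test_empty_is_zero(self):
        assert compute_volume(_mask_from_count(0)) == 0.0

    def test_additive_over_disjoint(self):
        a = _mask_from_count(123)
        b = _mask_from_count(77, offset=400)
        merged = a.with_voxels(a.voxels | b.voxels)
        assert compute_volume(merged) == pytest.approx(
            compute_volume(a) + compute_volume(b)
        )


class TestSpearman:
    def test_monotone_is_plus_minus_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, [2.0, 3.0, 8.0, 20.0]) == pytest.approx(1.0)
        assert spearman_rho(x, [20.0, 8.0, 3.0, 2.0]) == pytest.approx(-1.0)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(1)
        xs = rng.normal(size=10)
        ys = rng.normal(size=10)
        expected = stats.spearmanr(xs, ys).statistic
        assert spearman_rho(xs, ys) == pytest.approx(expected)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)


def _enumerate_signed_rank_p(diffs):
    """Oracle: exact two-sided p over all 2^n equiprobable sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            stat, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_five_positive_differences_exact(self):
        xs = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        ys = np.zeros(5)
        stat, p = wilcoxon_signed_rank(xs, ys)
        assert stat == 15.0
        assert p == pytest.approx(2 / 32)  # one tail 1/32, two-sided 0.0625

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        xs = rng.normal(size=n)
        ys = rng.normal(size=n)
        if seed % 2:  # force ties in |differences| sometimes
            xs = np.round(xs - ys, 1) + ys
        _, p = wilcoxon_signed_rank(xs, ys)
        assert p == pytest.approx(_enumerate_signed_rank_p(xs - ys))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        xs, ys = rng.normal(size=12), rng.normal(size=12)
        _, p = wilcoxon_signed_rank(xs, ys)
        expected = stats.wilcoxon(xs, ys, method="exact").pvalue
        assert p == pytest.approx(expected)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(12)
        xs = rng.normal(size=40)
        ys = xs + rng.normal(0.3, 1.0, size=40)
        _, p = wilcoxon_signed_rank(xs, ys)
        expected = stats.wilcoxon(xs, ys, method="approx", correction=False).pvalue
        assert p == pytest.approx(expected, rel=1e-6)


class TestVolumeErrorStats:
    def test_identity_all_zero(self):
        out = volume_error_stats([1.0, 2.0], [1.0, 2.0])
        assert out["mean_signed_pct"] == 0.0
        assert out["mean_squared_diff"] == 0.0
        assert out["rmse"] == 0.0

    def test_cohort_mean_overestimation_percentage(self):
        """Cohort means 239 vs 308 cm^3 correspond to +28.9%."""
        truth = [239.0] * 4
        pred = [308.0] * 4
        out = volume_error_stats(pred, truth)
        assert round(out["mean_signed_pct"], 1) == 28.9

    def test_constant_shift_rmse(self):
        truth = np.array([10.0, 20.0, 30.0])
        out = volume_error_stats(truth + 4.0, truth)
        assert out["rmse"] == pytest.approx(4.0)


class TestFolds:
    def test_thirtyfour_cases_five_folds(self):
        ids = [f"c{i:02d}" for i in range(34)]
        folds = make_folds(ids, k=5, seed=0)
        sizes = sorted(len(f.test_ids) for f in folds)
        assert sizes == [6, 7, 7, 7, 7]
        tested = [c for f in folds for c in f.test_ids]
        assert sorted(tested) == sorted(ids)  # partition: each case once
        for f in folds:
            assert not set(f.test_ids) & set(f.train_ids)
            assert sorted(f.test_ids + f.train_ids) == sorted(ids)

    def test_seed_reproducibility(self):
        ids = [f"c{i}" for i in range(10)]
        f1 = make_folds(ids, k=5, seed=3)
        f2 = make_folds(ids, k=5, seed=3)
        assert [f.test_ids for f in f1] == [f.test_ids for f in f2]

    def test_fewer_cases_than_folds_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds(["a", "b"], k=5, seed=0)


def test_bootstrap_ci_brackets_median():
    rng = np.random.default_rng(0)
    values = rng.normal(10.0, 2.0, size=50)
    med, lo, hi = bootstrap_median_ci(values, n_boot=2000, seed=1)
    assert lo <= med <= hi
    assert med == pytest.approx(np.median(values))
    # seeded: identical reruns
    assert bootstrap_median_ci(values, n_boot=2000, seed=1) == (med, lo, hi)
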