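"""2.5D sampling, loss definitions, and adversarial training behaviour."""

import numpy as np
import pytest

from psoasseg import BinaryMask, ImageVolume, dsc
from psoasseg.gan import (
    GanConfig,
    Generator,
    build_slice_samples,
    gan_loss,
    l1_loss,
    predict_volume,
    total_loss,
    train,
)


def _thin_volume(n_slices, ny=16, nx=16, seed=0):
    rng = np.random.default_rng(seed)
    vox = rng.normal(0, 50, (n_slices, ny, nx)).astype(np.float32)
    vol = ImageVolume(vox, (2, 2, 5), case_id=f"thin{n_slices}")
    mask = BinaryMask(rng.random((n_slices, ny, nx)) < 0.2, (2, 2, 5))
    return vol, mask


class TestSliceSampling:
    @pytest.mark.parametrize("n_slices,expected", [(76, 74), (3, 1), (10, 8)])
    def test_interior_slice_count(self, n_slices, expected):
        vol, mask = _thin_volume(n_slices)
        cfg = GanConfig.desk(train_size=32)
        samples = build_slice_samples(vol, mask, cfg)
        assert len(samples) == expected

    def test_minimal_volume_channels_are_the_three_slices(self):
        vol, mask = _thin_volume(3, ny=32, nx=32)
        cfg = GanConfig.desk(train_size=32)
        (sample,) = build_slice_samples(vol, mask, cfg)
        assert sample.z == 2  # 1-based active slice
        from psoasseg.gan import _normalize_hu

        norm = _normalize_hu(vol.voxels)
        for ch, z in zip(range(3), (0, 1, 2)):
            np.testing.assert_allclose(sample.image[ch], norm[z], atol=1e-6)

    def test_labels_stay_binary_after_resize(self):
        vol, mask = _thin_volume(5, ny=24, nx=24)
        cfg = GanConfig.desk(train_size=32)
        for s in build_slice_samples(vol, mask, cfg):
            assert s.label.dtype == bool

    def test_cohort_sample_total_conserved(self, small_cohort):
        cfg = GanConfig.desk()
        total = sum(
            len(build_slice_samples(v, m, cfg)) for v, m in small_cohort
        )
        assert total == sum(v.n_slices - 2 for v, _ in small_cohort)


class TestLosses:
    def test_l1_identity_is_zero(self):
        x = np.random.default_rng(0).random((4, 4))
        assert l1_loss(x, x) == 0.0

    def test_l1_constant_difference(self):
        x = np.zeros((8, 8))
        assert l1_loss(x + 0.37, x) == pytest.approx(0.37)

    def test_l1_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((4, 4)), rng.random((4, 4))
        brute = sum(abs(b[i, j] - a[i, j]) for i in range(4) for j in range(4)) / 16
        assert l1_loss(a, b) == pytest.approx(brute)

    def test_gan_loss_matches_brute_force(self):
        rng = np.random.default_rng(6)
        d_real = rng.uniform(0.05, 0.95, (2, 3, 3))
        d_fake = rng.uniform(0.05, 0.95, (2, 3, 3))
        brute = np.mean([np.log(v) for v in d_real.ravel()]) + np.mean(
            [np.log(1 - v) for v in d_fake.ravel()]
        )
        assert gan_loss(d_real, d_fake) == pytest.approx(brute)

    def test_gan_loss_rejects_out_of_range(self):
        ok = np.full((2, 2), 0.5)
        with pytest.raises(ValueError, match="strictly"):
            gan_loss(np.array([[0.0, 0.5], [0.5, 0.5]]), ok)

    def test_total_weighs_l1_ten_to_one(self):
        cfg = GanConfig.desk()
        assert total_loss(l_gan=-1.0, l_l1=0.2, cfg=cfg) == pytest.approx(
            1.0 * -1.0 + 10.0 * 0.2
        )

    def test_l1_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            l1_loss(np.array([np.nan]), np.array([0.0]))


class TestTraining:
    def test_zero_epochs_returns_valid_untrained_generator(self, phantom_case):
        vol, gt = phantom_case
        cfg = GanConfig.desk(epochs=0, seed=0)
        samples = build_slice_samples(vol, gt, cfg)
        result = train(samples, cfg)
        assert result.trace == []
        pred = predict_volume(vol, result, cfg)
        assert pred.shape == vol.shape
        assert pred.spacing == vol.spacing
        assert pred.voxels.dtype == bool

    def test_identical_seed_reproduces_loss_trace(self):
        vol, mask = _thin_volume(4, ny=32, nx=32, seed=3)
        cfg = GanConfig.desk(train_size=32, epochs=2, base_channels=4, seed=9)
        samples = build_slice_samples(vol, mask, cfg)
        t1 = train(samples, cfg).trace
        t2 = train(samples, cfg).trace
        assert t1 == t2

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            train([], GanConfig.desk())

    def test_memorization_reduces_l1(self, memorization_run):
        """Overfitting a single exam drives the pixel loss well below its
        starting value and reproduces the exam's own segmentation."""
        result, cfg, vol, gt = memorization_run
        assert result.trace[-1]["l1"] < result.trace[0]["l1"]
        pred = predict_volume(vol, result, cfg)
        assert dsc(pred, gt) > 0.5


class TestPrediction:
    class _ConstantGenerator:
        def __init__(self, value):
            self.value = value

        def forward(self, x):
            return np.full((x.shape[0], 1, x.shape[2], x.shape[3]), self.value,
                           dtype=np.float32)

    def test_all_zero_output_gives_empty_mask(self, phantom_case):
        vol, _ = phantom_case
        cfg = GanConfig.desk()
        pred = predict_volume(vol, self._ConstantGenerator(0.0), cfg)
        assert pred.count == 0

    def test_all_one_output_fills_grid(self, phantom_case):
        vol, _ = phantom_case
        cfg = GanConfig.desk()
        pred = predict_volume(vol, self._ConstantGenerator(1.0), cfg)
        assert pred.count == np.prod(vol.shape)

    def test_prediction_binary_and_grid_preserving(self, memorization_run):
        result, cfg, vol, _ = memorization_run
        pred = predict_volume(vol, result, cfg)
        assert pred.shape == vol.shape
        assert set(np.unique(pred.voxels.astype(int))) <= {0, 1}


def test_generator_state_round_trip(tmp_path):
    from psoasseg.gan import load_generator, save_generator, train

    vol, mask = _thin_volume(4, ny=32, nx=32, seed=1)
    cfg = GanConfig.desk(train_size=32, epochs=1, base_channels=4, seed=2)
    result = train(build_slice_samples(vol, mask, cfg), cfg)
    save_generator(result, tmp_path / "model.npz")
    loaded = load_generator(tmp_path / "model.npz")
    x = np.random.default_rng(0).random((1, 3, 32, 32)).astype(np.float32)
    np.testing.assert_allclose(
        result.generator.forward(x), loaded.generator.forward(x), atol=1e-6
    )
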