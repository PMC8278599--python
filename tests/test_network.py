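"""Network shapes, loss functions, and desk-scale training behaviour."""

import numpy as np
import pytest

import hahnfusion as hf
from hahnfusion.network import EXTRACTOR_SPECS, RECONSTRUCTOR_SPECS


class TestArchitecture:
    def test_layer_table(self):
        assert [(s.kernel_count, s.kernel_size, s.stride, s.padding)
                for s in EXTRACTOR_SPECS] == [
            (64, 7, 1, 3), (64, 5, 1, 2), (64, 3, 1, 1)]
        assert [(s.kernel_count, s.kernel_size, s.stride, s.padding)
                for s in RECONSTRUCTOR_SPECS] == [
            (64, 3, 1, 1), (3, 1, 1, 0)]

    def test_same_seed_same_weights(self):
        n1, n2 = hf.build_network(5), hf.build_network(5)
        for p, q in zip(n1.params, n2.params):
            assert np.array_equal(p.data, q.data)

    def test_extract_preserves_spatial_size(self, rng):
        net = hf.build_network(0)
        feats = hf.extract_features(net, rng.random((37, 41, 3)))
        assert feats.shape == (64, 37, 41)

    def test_roundtrip_shapes(self, rng):
        net = hf.build_network(0)
        img = rng.random((64, 64, 3))
        out = hf.reconstruct_image(net, hf.extract_features(net, img))
        assert out.shape == (64, 64, 3)
        assert out.min() > 0 and out.max() < 1  # sigmoid output range

    def test_zero_image_zero_bias_gives_zero_features(self):
        net = hf.build_network(0)  # biases initialize to zero
        feats = hf.extract_features(net, np.zeros((16, 16, 3)))
        assert np.all(feats == 0)

    def test_forward_deterministic(self, rng):
        net = hf.build_network(3)
        img = rng.random((32, 32, 3))
        assert np.array_equal(hf.extract_features(net, img),
                              hf.extract_features(net, img))

    def test_wrong_channel_count_rejected(self, rng):
        net = hf.build_network(0)
        with pytest.raises(ValueError, match="H, W, 3"):
            hf.extract_features(net, rng.random((16, 16)))
        with pytest.raises(ValueError, match="64"):
            hf.reconstruct_image(net, rng.random((32, 16, 16)))


class TestLosses:
    def test_cross_entropy_hand_value(self):
        assert hf.loss_cross_entropy(np.array([[0.5]]), np.array([[0.5]])) \
            == pytest.approx(np.log(2), abs=1e-9)

    def test_cross_entropy_minimized_at_output_equal_input(self, rng):
        I = np.full((8, 8), 0.5)
        base = hf.loss_cross_entropy(I, I)
        for o in np.linspace(0.05, 0.95, 19):
            if abs(o - 0.5) > 1e-12:
                assert hf.loss_cross_entropy(I, np.full((8, 8), o)) > base
        # seeded random images: loss(I, I) <= loss(I, O)
        I = rng.random((16, 16))
        for _ in range(5):
            O = rng.random((16, 16))
            assert hf.loss_cross_entropy(I, I) <= hf.loss_cross_entropy(I, O)

    def test_ms_ssim_identity_and_symmetry(self, rng):
        I = rng.random((64, 64))
        assert hf.loss_ms_ssim(I, I) == pytest.approx(0.0, abs=1e-9)
        O = rng.random((64, 64))
        assert hf.loss_ms_ssim(I, O) == pytest.approx(hf.loss_ms_ssim(O, I),
                                                      abs=1e-12)

    def test_ms_ssim_orders_degradations(self, rng):
        I = (rng.random((64, 64)) > 0.5).astype(float)
        noisy = np.clip(I + rng.normal(0, 0.01, I.shape), 0, 1)
        assert hf.loss_ms_ssim(I, 1 - I) > hf.loss_ms_ssim(I, noisy)

    def test_tv_constant_zero(self):
        assert hf.loss_tv(np.full((10, 10), 0.3)) == 0.0

    def test_tv_hand_value_raw_sum(self):
        F = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert hf.loss_tv(F, reduction="sum") == pytest.approx(2.0)

    def test_tv_decreases_under_smoothing(self, rng):
        X = rng.random((32, 32))
        k = np.ones((3, 3)) / 9.0
        from scipy.ndimage import convolve
        assert hf.loss_tv(convolve(X, k, mode="nearest")) <= hf.loss_tv(X)

    def test_total_is_sum_of_components(self, rng):
        I = rng.random((64, 64, 3))
        O = rng.random((64, 64, 3))
        total, (ce, ms, tv) = hf.loss_total(I, O, return_components=True)
        assert total == pytest.approx(ce + ms + tv, abs=1e-12)
        assert total >= 0 and ce >= 0 and ms >= 0 and tv >= 0

    def test_total_constant_half_is_ln2(self):
        I = np.full((32, 32), 0.5)
        assert hf.loss_total(I, I) == pytest.approx(np.log(2), abs=1e-7)


class TestTraining:
    def tiny_images(self, n=8, size=32, seed=2):
        r = np.random.default_rng(seed)
        return [r.random((size, size, 3)).astype(np.float32)
                for _ in range(n)]

    def test_zero_epochs_leaves_weights_unchanged(self):
        net = hf.build_network(1)
        before = [p.data.copy() for p in net.params]
        net, hist = hf.train_autoencoder(net, self.tiny_images(),
                                         hf.TrainConfig(epochs=0))
        assert hist == []
        for p, b in zip(net.params, before):
            assert np.array_equal(p.data, b)

    def test_loss_decreases_on_tiny_task(self):
        net = hf.build_network(1)
        net, hist = hf.train_autoencoder(
            net, self.tiny_images(), hf.TrainConfig(epochs=5, batch_size=4,
                                                    seed=1))
        assert hist[-1] < hist[0]

    def test_identical_seeds_give_identical_runs(self):
        hists, weights = [], []
        for _ in range(2):
            net = hf.build_network(9)
            net, hist = hf.train_autoencoder(
                net, self.tiny_images(n=4),
                hf.TrainConfig(epochs=2, batch_size=2, seed=9))
            hists.append(hist)
            weights.append([p.data.copy() for p in net.params])
        assert hists[0] == hists[1]
        for p, q in zip(*weights):
            assert np.array_equal(p, q)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hf.train_autoencoder(hf.build_network(0), [])

    def test_checkpoint_roundtrip(self, tmp_path):
        net = hf.build_network(4)
        path = tmp_path / "w.npz"
        hf.save_weights(net, path)
        loaded = hf.load_weights(path)
        for p, q in zip(net.params, loaded.params):
            assert np.array_equal(p.data, q.data)
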