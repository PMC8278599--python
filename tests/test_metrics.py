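"""Fusion-quality metric sanity and hand-computed values."""

import numpy as np
import pytest

import hahnfusion as hf
from hahnfusion.metrics import _kl_bits


def textured(seed=0, size=64):
    r = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter
    img = gaussian_filter(r.random((size, size)), 1.0)
    return (img - img.min()) / (img.max() - img.min())


class TestSF:
    def test_constant_zero(self):
        assert hf.metric_sf(np.full((8, 8), 0.4)) == 0.0

    def test_hand_value_2x2(self):
        assert hf.metric_sf(np.array([[0.0, 1.0], [0.0, 1.0]])) == \
            pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_scales_linearly(self, rng):
        F = rng.random((16, 16))
        assert hf.metric_sf(0.37 * F) == pytest.approx(
            0.37 * hf.metric_sf(F), rel=1e-12)


class TestSSIM:
    def test_self_similarity_is_one(self):
        I = textured(1)
        assert hf.metric_ssim(I, I) == pytest.approx(1.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        """Zero-variance limit: only the luminance term differs from 1."""
        c1, c2, C1 = 0.5, 0.25, 1e-4
        expect = (2 * c1 * c2 + C1) / (c1**2 + c2**2 + C1)
        got = hf.metric_ssim(np.full((16, 16), c1), np.full((16, 16), c2))
        assert got == pytest.approx(expect, abs=1e-9)
        assert got == pytest.approx(0.8001, abs=1e-3)

    def test_symmetric(self, rng):
        X, Y = rng.random((32, 32)), rng.random((32, 32))
        assert hf.metric_ssim(X, Y) == pytest.approx(hf.metric_ssim(Y, X),
                                                     abs=1e-12)


class TestCE:
    def test_identical_images_zero(self):
        I = textured(2)
        t = hf.FusionTriplet(I, I, I)
        assert hf.metric_ce(t) == pytest.approx(0.0, abs=1e-6)

    def test_nonnegative(self, rng):
        t = hf.FusionTriplet(rng.random((32, 32)), rng.random((32, 32)),
                             rng.random((32, 32)))
        assert hf.metric_ce(t) >= 0

    def test_two_bin_hand_case(self):
        """(0.5, 0.5) vs (0.25, 0.75) -> 0.5·log2(2) + 0.5·log2(2/3)."""
        p = np.array([0.5, 0.5])
        q = np.array([0.25, 0.75])
        expect = 0.5 * np.log2(2) + 0.5 * np.log2(0.5 / 0.75)
        assert _kl_bits(p, q) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.2075, abs=1e-4)
        # same case through images: half 0 / half 1 vs quarter 0
        A = np.zeros((16, 16))
        A[:8] = 1.0
        F = np.zeros((16, 16))
        F[:12] = 1.0
        ce = hf.metric_ce(hf.FusionTriplet(A, A, F))
        assert ce == pytest.approx(expect, abs=1e-3)


class TestQabf:
    def test_perfect_transfer_when_fused_equals_sources(self):
        I = textured(3)
        assert hf.metric_qabf(hf.FusionTriplet(I, I, I)) > 0.95

    def test_constant_fused_transfers_nothing(self):
        A, B = textured(4), textured(5)
        q = hf.metric_qabf(hf.FusionTriplet(A, B, np.full_like(A, 0.5)))
        assert q < 0.1

    def test_bounded(self, rng):
        for _ in range(3):
            t = hf.FusionTriplet(rng.random((24, 24)), rng.random((24, 24)),
                                 rng.random((24, 24)))
            assert 0.0 <= hf.metric_qabf(t) <= 1.0


class TestVIF:
    def test_self_fidelity_is_one(self):
        I = textured(6)
        assert hf.metric_vif(I, I) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_noise(self):
        I = textured(7)
        r = np.random.default_rng(8)
        weak = np.clip(I + r.normal(0, 0.02, I.shape), 0, 1)
        strong = np.clip(I + r.normal(0, 0.3, I.shape), 0, 1)
        assert hf.metric_vif(I, strong) < hf.metric_vif(I, weak)

    def test_nonnegative(self, rng):
        assert hf.metric_vif(rng.random((40, 40)), rng.random((40, 40))) >= 0


class TestFMI:
    def test_true_fusion_beats_degenerate_candidates(self):
        A = textured(9)
        r = np.random.default_rng(10)
        shuffled = A.ravel().copy()
        r.shuffle(shuffled)
        candidates = [A, shuffled.reshape(A.shape), np.full_like(A, 0.5)]
        scores = [hf.metric_fmi(hf.FusionTriplet(A, A, F))
                  for F in candidates]
        assert scores[0] == max(scores)

    def test_bounded_and_symmetric(self, rng):
        A, B, F = (rng.random((32, 32)) for _ in range(3))
        s1 = hf.metric_fmi(hf.FusionTriplet(A, B, F))
        s2 = hf.metric_fmi(hf.FusionTriplet(B, A, F))
        assert 0.0 <= s1 <= 1.0
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestScoreAll:
    def test_report_and_csv(self, tmp_path):
        A, B = textured(11), textured(12)
        F = 0.5 * (A + B)
        rep = hf.score_all(hf.FusionTriplet(A, B, F))
        assert -1 <= rep.ssim <= 1 and 0 <= rep.qabf <= 1
        assert 0 <= rep.fmi <= 1 and rep.sf >= 0 and rep.ce >= 0
        assert rep.vif >= 0
        out = tmp_path / "scores.csv"
        hf.write_scores_csv({"pair0": rep}, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("id,qabf,ssim")
        assert lines[1].startswith("pair0,")

    def test_color_inputs_reduced_to_luminance(self, rng):
        A = rng.random((32, 32, 3))
        B = rng.random((32, 32))
        F = rng.random((32, 32, 3))
        rep = hf.score_all(hf.FusionTriplet(A, B, F))
        assert np.isfinite(list(rep.as_dict().values())).all()

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            hf.FusionTriplet(rng.random((16, 16)), rng.random((16, 16)),
                             rng.random((8, 8)))
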