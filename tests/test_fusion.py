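"""Block partition, potential energy, saliency, and the fusion rule."""

import numpy as np
import pytest

import hahnfusion as hf
from conftest import (hahn_moments_bruteforce, pcnn_oracle,
                      potential_energy_bruteforce)


class TestPartition:
    def test_exact_tiling_no_padding(self):
        grid = hf.partition_blocks(np.arange(256.0).reshape(16, 16), 8)
        assert grid.grid_shape == (2, 2)
        assert grid.pad_rows == grid.pad_cols == 0

    def test_zero_fill_to_multiple(self):
        grid = hf.partition_blocks(np.ones((10, 10)), 8)
        assert grid.grid_shape == (2, 2)
        assert (grid.pad_rows, grid.pad_cols) == (6, 6)
        # the fill really is zeros
        assert np.all(grid.blocks[1, 1][2:, 2:] == 0)

    def test_reassemble_roundtrip(self, rng):
        X = rng.random((20, 24))
        assert np.array_equal(hf.reassemble_blocks(hf.partition_blocks(X, 8)),
                              X)

    def test_small_block_side_rejected(self):
        with pytest.raises(ValueError, match="D"):
            hf.partition_blocks(np.ones((8, 8)), 1)


class TestPotentialEnergy:
    def test_hand_example(self):
        assert hf.potential_energy(np.array([[1.0, 3.0], [2.0, 1.0]])) == \
            pytest.approx(3.0, abs=1e-12)

    def test_uniform_moments_have_zero_energy(self):
        assert hf.potential_energy(np.full((6, 6), 2.7)) == 0.0

    def test_zero_block_has_zero_energy(self):
        b = hf.hahn_basis(hf.HahnParams(8))
        H = hf.hahn_moments_2d(np.zeros((8, 8)), b, b)
        assert hf.potential_energy(H) == 0.0

    def test_matches_bruteforce(self, rng):
        H = rng.normal(size=(8, 8))
        assert hf.potential_energy(H) == pytest.approx(
            potential_energy_bruteforce(H), rel=1e-12)


class TestSaliency:
    def test_constant_image_uniform(self):
        s = hf.cws_saliency(np.full((32, 32), 0.6))
        assert len(np.unique(s)) == 1

    def test_textured_half_more_salient(self, rng):
        img = np.full((64, 64), 0.5)
        img[:, 32:] = rng.random((64, 32))
        s = hf.cws_saliency(img)
        assert s[:, 40:].mean() > s[:, :24].mean()
        assert s.min() >= 0 and s.max() <= 1

    def test_shape_and_errors(self):
        assert hf.cws_saliency(np.zeros((33, 47))).shape == (33, 47)
        with pytest.raises(ValueError):
            hf.cws_saliency(np.zeros((0, 0)))


class TestBlockLinkStrength:
    def test_uniform(self):
        out = hf.block_link_strength(np.full((16, 16), 0.4), 8)
        assert np.allclose(out, 0.4)
        assert out.shape == (2, 2)

    def test_checkerboard_mean(self):
        cb = np.indices((16, 16)).sum(axis=0) % 2
        assert np.allclose(hf.block_link_strength(cb.astype(float), 8), 0.5)

    def test_matches_loop_mean(self, rng):
        sal = rng.random((24, 16))
        out = hf.block_link_strength(sal, 8)
        for i in range(3):
            for j in range(2):
                assert out[i, j] == pytest.approx(
                    sal[8 * i:8 * (i + 1), 8 * j:8 * (j + 1)].mean())


class TestFuseFeatureMaps:
    def test_idempotent_on_identical_inputs(self, rng):
        A = rng.normal(size=(4, 32, 32))
        fused = hf.fuse_feature_maps([A, A], D=8)
        assert np.array_equal(fused, A)

    def test_permutation_invariant(self, rng):
        A = rng.normal(size=(2, 16, 16))
        B = rng.normal(size=(2, 16, 16))
        f1 = hf.fuse_feature_maps([A, B], D=8)
        f2 = hf.fuse_feature_maps([B, A], D=8)
        assert np.array_equal(f1, f2)

    def test_tie_takes_elementwise_max(self):
        """Two sources with identical activity (swapped channels) tie on
        every block; the fused block is max(A, B)."""
        a1 = np.array([[1.0, 5.0]])
        a2 = np.array([[4.0, 2.0]])
        A = np.stack([a1, a2])  # channels (a1, a2)
        B = np.stack([a2, a1])  # same |mean| activity, channels swapped
        fused = hf.fuse_feature_maps([A, B], D=8)
        expect = np.maximum(A, B)  # both channels -> [[4, 5]]
        assert np.array_equal(fused, expect)
        assert np.array_equal(fused[0], np.array([[4.0, 5.0]]))

    def test_padding_never_leaks(self, rng):
        A = rng.normal(size=(3, 20, 28))
        B = rng.normal(size=(3, 20, 28))
        assert hf.fuse_feature_maps([A, B], D=8).shape == (3, 20, 28)

    def test_blocks_are_verbatim_or_max(self, rng):
        A = rng.normal(size=(1, 16, 16))
        B = rng.normal(size=(1, 16, 16))
        fused = hf.fuse_feature_maps([A, B], D=8)
        for i in range(2):
            for j in range(2):
                blk = fused[0, 8 * i:8 * (i + 1), 8 * j:8 * (j + 1)]
                cand = [A[0, 8 * i:8 * (i + 1), 8 * j:8 * (j + 1)],
                        B[0, 8 * i:8 * (i + 1), 8 * j:8 * (j + 1)]]
                ok = any(np.array_equal(blk, c) for c in cand) or \
                    np.array_equal(blk, np.maximum(*cand))
                assert ok

    def test_texture_routing_matches_bruteforce_pipeline(self, rng):
        """A has texture in the left block, B in the right; the fused map
        must take each block from the textured source, and the whole
        decision must match an independently coded pipeline."""
        D = 8
        noise_l = rng.random((D, D))
        noise_r = rng.random((D, D))
        A = np.zeros((1, D, 2 * D))
        B = np.zeros((1, D, 2 * D))
        A[0, :, :D] = noise_l   # textured left, dark background right
        B[0, :, D:] = noise_r   # dark background left, textured right
        fused, details = hf.fuse_feature_maps([A, B], D=D,
                                              return_details=True)
        assert np.array_equal(fused[0, :, :D], noise_l)
        assert np.array_equal(fused[0, :, D:], noise_r)
        assert details["winner"].tolist() == [[0, 1]]

        # independent pipeline: moments + PE by loops, PCNN by simulation
        basis = hf.hahn_basis(hf.HahnParams(D))
        pes = []
        for stack in (A, B):
            act = np.abs(stack).mean(axis=0)
            pe = np.empty((1, 2))
            for j in range(2):
                H = hahn_moments_bruteforce(act[:, D * j:D * (j + 1)], basis)
                pe[0, j] = potential_energy_bruteforce(H)
            pes.append(pe)
        lo = min(p.min() for p in pes)
        hi = max(p.max() for p in pes)
        stim = [(p - lo) / (hi - lo) for p in pes]
        acts = [np.abs(s).mean(axis=0) for s in (A, B)]
        amin = min(a.min() for a in acts)
        amax = max(a.max() for a in acts)
        cfg = hf.PCNNConfig()
        counts = []
        for stack, act, st in zip((A, B), acts, stim):
            sal = hf.cws_saliency((act - amin) / (amax - amin))
            beta = hf.block_link_strength(sal, D)
            c, _ = pcnn_oracle(st, beta, cfg)
            counts.append(c)
        assert np.array_equal(np.stack(counts),
                              details["firing_counts"])
        winner = np.argmax(np.stack(counts), axis=0)
        assert winner.tolist() == [[0, 1]]

    def test_three_sources(self, rng):
        maps = [rng.normal(size=(2, 16, 16)) for _ in range(3)]
        fused = hf.fuse_feature_maps(maps, D=8)
        assert fused.shape == (2, 16, 16)
        # idempotence also holds for k = 3
        same = hf.fuse_feature_maps([maps[0]] * 3, D=8)
        assert np.array_equal(same, maps[0])

    def test_errors(self, rng):
        A = rng.normal(size=(2, 16, 16))
        with pytest.raises(ValueError, match="at least 2"):
            hf.fuse_feature_maps([A], D=8)
        with pytest.raises(ValueError, match="shape"):
            hf.fuse_feature_maps([A, rng.normal(size=(2, 8, 8))], D=8)
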