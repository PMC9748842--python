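import math

import numpy as np
import pytest

from homopoint.core import PointSet, pad_points
from homopoint.model import (
    HomologousPointNet,
    ModelConfig,
    compute_offsets,
    count_parameters,
    patch_centers,
    patch_index,
    similarity_heatmap,
)
from homopoint.nn.autodiff import Tensor


from naive_oracles import naive_gather, naive_offsets, naive_similarity, naive_soft_argmax


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(image_size=100, patch_size=16)
        with pytest.raises(ValueError):
            ModelConfig(patch_size=6)
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=30, n_heads=4)

    def test_default_n_patches(self):
        cfg = ModelConfig()
        assert cfg.n_patches == (512 // 16) ** 2 == 1024

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="ptach_size"):
            ModelConfig.from_dict({"ptach_size": 8})


class TestEmbedPatches:
    def test_default_config_shape(self):
        """512x512 input with p=16, d=128 embeds to 1024 x 128."""
        cfg = ModelConfig()
        net = HomologousPointNet(cfg, seed=0)
        out = net.embed_patches(np.zeros((512, 512)), "histology")
        assert out.shape == (1024, 128)

    def test_zero_image_zero_pos_embedding_rows_identical(self, tiny_net):
        net = tiny_net
        saved = net.params["histology/pos"].data.copy()
        net.params["histology/pos"].data[:] = 0.0
        out = net.embed_patches(np.zeros((64, 64)), "histology").data
        net.params["histology/pos"].data[:] = saved
        assert np.abs(out - out[0]).max() < 1e-12

    def test_single_patch_isolation_oracle(self, tiny_net, rng):
        """Each row equals the CNN applied to that patch alone (pre position)."""
        cfg = tiny_net.config
        img = rng.random((64, 64))
        full = tiny_net.embed_patches(img, "mr").data - tiny_net.params["mr/pos"].data
        p, g = cfg.patch_size, cfg.grid
        for idx in [0, 5, g * g - 1]:
            iy, ix = divmod(idx, g)
            patch = img[iy * p : (iy + 1) * p, ix * p : (ix + 1) * p]
            tile = np.zeros((64, 64))
            tile[:p, :p] = patch
            row = tiny_net.embed_patches(tile, "mr").data[0] - tiny_net.params["mr/pos"].data[0]
            assert np.abs(row - full[idx]).max() < 1e-5

    def test_wrong_shape_raises(self, tiny_net):
        with pytest.raises(ValueError, match="size"):
            tiny_net.embed_patches(np.zeros((32, 32)), "histology")


class TestEncoderBlocks:
    def test_shape_preserved(self):
        net = HomologousPointNet(ModelConfig(image_size=512, patch_size=16, embed_dim=128, n_blocks=1), seed=0)
        emb = Tensor(np.random.default_rng(0).standard_normal((1024, 128)))
        out = net.local_vit_block(emb, "histology", 0)
        assert out.shape == (1024, 128)

    def test_reshape_round_trip_is_identity(self, rng):
        x = rng.standard_normal((64, 16))
        assert np.array_equal(x.reshape(8, 8, 16).reshape(64, 16), x)

    def test_identity_attention_zero_ffn_doubles_input(self, rng):
        cfg = ModelConfig(image_size=64, patch_size=8, embed_dim=16, n_blocks=1, n_heads=2, use_layernorm=False)
        net = HomologousPointNet(cfg, seed=3)
        x = rng.standard_normal((64, 16))
        out = net.local_vit_block(Tensor(x), "mr", 0, identity_attention=True, zero_ffn=True)
        assert np.abs(out.data - 2 * x).max() < 1e-12

    def test_six_blocks_reduce_to_64x(self, rng):
        cfg = ModelConfig(image_size=64, patch_size=8, embed_dim=16, n_blocks=6, n_heads=2, use_layernorm=False)
        net = HomologousPointNet(cfg, seed=3)
        x = rng.standard_normal((64, 16))
        out = net.encode(Tensor(x), "histology", identity_attention=True, zero_ffn=True)
        assert np.abs(out.data - (2**6) * x).max() < 1e-9

    def test_zero_blocks_identity(self, rng):
        cfg = ModelConfig(image_size=64, patch_size=8, embed_dim=16, n_blocks=0)
        net = HomologousPointNet(cfg, seed=0)
        x = rng.standard_normal((64, 16))
        assert np.array_equal(net.encode(Tensor(x), "mr").data, x)

    def test_branches_differ(self, tiny_net, rng):
        x = Tensor(rng.standard_normal((64, 16)))
        a = tiny_net.encode(x, "histology").data
        b = tiny_net.encode(x, "mr").data
        assert np.abs(a - b).max() > 0

    def test_non_square_token_count_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="square"):
            tiny_net.local_vit_block(Tensor(np.zeros((60, 16))), "mr", 0)


class TestPointCalculation:
    def test_gather_examples(self, tiny_net):
        cfg = tiny_net.config
        enc = Tensor(np.random.default_rng(0).standard_normal((cfg.n_patches, cfg.embed_dim)))
        X = pad_points(PointSet(np.array([[0.0, 0.0]])), cfg.L)
        out = tiny_net.gather_landmark_embeddings(enc, X)
        assert np.allclose(out.data[0], enc.data[0])

    def test_gather_flat_index_convention(self):
        # p=16, grid width 32: the patch containing (37, 5) is (2, 0) -> 64
        assert patch_index(np.array([[37.0, 5.0]]), 16, 32)[0] == 64

    def test_gather_against_naive_loop(self, tiny_net, rng):
        cfg = tiny_net.config
        enc = rng.standard_normal((cfg.n_patches, cfg.embed_dim))
        X = rng.uniform(0, cfg.image_size - 1e-9, (cfg.L, 2))
        got = tiny_net.gather_landmark_embeddings(Tensor(enc), PointSet(X)).data
        assert np.allclose(got, naive_gather(X=X, enc_m=enc, p=cfg.patch_size, grid=cfg.grid))

    def test_gather_out_of_bounds_raises(self, tiny_net):
        X = pad_points(PointSet(np.array([[70.0, 100.0]])), tiny_net.config.L)
        enc = Tensor(np.zeros((tiny_net.config.n_patches, 16)))
        with pytest.raises(ValueError, match="outside"):
            tiny_net.gather_landmark_embeddings(enc, X)

    def test_offsets_examples(self):
        # patch-center case: point exactly at (p/2, p/2) has zero offset
        assert np.allclose(compute_offsets(np.array([[8.0, 8.0]]), 16), [[0.0, 0.0]])
        # direct evaluation: p=16, X=(37,5) -> ((37 mod 16)-8, (5 mod 16)-8) = (-3,-3)
        assert np.allclose(compute_offsets(np.array([[37.0, 5.0]]), 16), [[-3.0, -3.0]])

    def test_offsets_range_property(self, rng):
        X = rng.uniform(0, 512, (1000, 2))
        O = compute_offsets(X, 16)
        assert O.min() >= -8 and O.max() < 8

    def test_similarity_rows_stochastic(self, tiny_net, rng):
        g = Tensor(rng.standard_normal((4, 16)))
        f = Tensor(rng.standard_normal((64, 16)))
        S = tiny_net.similarity(g, f).data
        assert np.abs(S.sum(axis=1) - 1).max() < 1e-6
        assert S.min() >= 0 and S.max() <= 1

    def test_similarity_hand_softmax(self, tiny_net):
        # logits (0, ln 3) -> probabilities (0.25, 0.75)
        g = np.zeros((1, 16))
        g[0, 0] = 1.0
        f = np.zeros((2, 16))
        f[1, 0] = math.log(3.0)
        S = tiny_net.similarity(Tensor(g), Tensor(f)).data
        assert np.allclose(S, [[0.25, 0.75]])

    def test_similarity_concentrates_on_matching_key(self, tiny_net):
        f = np.eye(16)[:8] * 100.0
        g = f[[3]]
        S = tiny_net.similarity(Tensor(g), Tensor(f)).data
        assert S[0, 3] > 0.99

    def test_similarity_dim_mismatch(self, tiny_net):
        with pytest.raises(ValueError, match="dimension"):
            tiny_net.similarity(Tensor(np.zeros((4, 8))), Tensor(np.zeros((64, 16))))

    def test_soft_argmax_one_hot_uniform_and_mixture(self):
        cfg = ModelConfig()  # default 512, p=16
        net = HomologousPointNet(ModelConfig(image_size=64, patch_size=8, embed_dim=16, n_blocks=0), seed=0)
        centers = patch_centers(cfg)
        L, N = 3, cfg.n_patches
        S = np.zeros((L, N))
        S[0, 37] = 1.0  # one-hot
        S[1, :] = 1.0 / N  # uniform
        S[2, 2] = 0.5
        S[2, 10] = 0.5
        net512 = HomologousPointNet.__new__(HomologousPointNet)
        net512.config = cfg
        out = net512.soft_argmax(Tensor(S)).data
        assert np.array_equal(out[0], centers[37])
        assert np.allclose(out[1], [256.0, 256.0])
        assert np.allclose(out[2], (centers[2] + centers[10]) / 2)

    def test_equation_oracles_random_instances(self, rng):
        """Gather, offsets, similarity and soft-argmax match naive loops."""
        cfg = ModelConfig(image_size=64, patch_size=8, embed_dim=16, n_blocks=0, L=4)
        net = HomologousPointNet(cfg, seed=0)
        for _ in range(20):
            enc_m = rng.standard_normal((cfg.n_patches, cfg.embed_dim))
            enc_f = rng.standard_normal((cfg.n_patches, cfg.embed_dim))
            X = rng.uniform(0, 64 - 1e-6, (4, 2))
            ps = PointSet(X)
            got_g = net.gather_landmark_embeddings(Tensor(enc_m), ps).data
            assert np.abs(got_g - naive_gather(enc_m, X, 8, 8)).max() < 1e-6
            assert np.abs(compute_offsets(X, 8) - naive_offsets(X, 8)).max() < 1e-6
            S = net.similarity(Tensor(got_g), Tensor(enc_f)).data
            assert np.abs(S - naive_similarity(got_g, enc_f)).max() < 1e-6
            got_y = net.soft_argmax(Tensor(S)).data
            assert np.abs(got_y - naive_soft_argmax(S, 8, 64)).max() < 1e-6


class TestForward:
    def test_all_sentinel_input_gives_all_zero_output(self, tiny_net):
        X = pad_points(PointSet(np.zeros((0, 2))), tiny_net.config.L)
        Y = tiny_net.predict_points(np.zeros((64, 64)), np.zeros((64, 64)), X)
        assert np.all(Y.coords == 0)

    def test_forward_matches_piecewise_composition(self, tiny_net, rng):
        cfg = tiny_net.config
        M, F = rng.random((64, 64)), rng.random((64, 64))
        X = pad_points(PointSet(rng.uniform(0, 63, (3, 2))), cfg.L)
        out = tiny_net.forward(M, F, X)
        enc_m = tiny_net.encode(tiny_net.embed_patches(M, "histology"), "histology")
        enc_f = tiny_net.encode(tiny_net.embed_patches(F, "mr"), "mr")
        g = tiny_net.gather_landmark_embeddings(enc_m, X)
        S = tiny_net.similarity(g, enc_f)
        y = tiny_net.soft_argmax(S).data + compute_offsets(X, cfg.patch_size)
        y[~X.valid] = 0.0
        assert np.abs(out["Y"].data - y).max() < 1e-5

    def test_padding_rows_never_influence_valid_rows(self, tiny_net, rng):
        cfg = tiny_net.config
        M, F = rng.random((64, 64)), rng.random((64, 64))
        coords = np.zeros((cfg.L, 2))
        coords[:2] = rng.uniform(4, 60, (2, 2))
        valid = np.zeros(cfg.L, dtype=bool)
        valid[:2] = True
        base = tiny_net.predict_points(M, F, PointSet(coords.copy(), valid.copy())).coords
        coords2 = coords.copy()
        coords2[2:] = rng.uniform(0, 60, (cfg.L - 2, 2))  # perturb sentinels
        pert = tiny_net.predict_points(M, F, PointSet(coords2, valid.copy())).coords
        assert np.array_equal(base[:2], pert[:2])
        assert np.all(pert[2:] == 0)

    def test_forward_deterministic(self, tiny_net, rng):
        M, F = rng.random((64, 64)), rng.random((64, 64))
        X = pad_points(PointSet(rng.uniform(0, 63, (3, 2))), tiny_net.config.L)
        a = tiny_net.predict_points(M, F, X).coords
        b = tiny_net.predict_points(M, F, X).coords
        assert np.abs(a - b).max() < 1e-7

    def test_valid_rows_inside_coordinate_hull(self, tiny_net, rng):
        cfg = tiny_net.config
        p = cfg.patch_size
        M, F = rng.random((64, 64)), rng.random((64, 64))
        X = pad_points(PointSet(rng.uniform(0, 63, (4, 2))), cfg.L)
        Y = tiny_net.predict_points(M, F, X)
        lo = p / 2 - math.floor(p / 2)
        hi = cfg.image_size - p / 2 + p - math.floor(p / 2)
        v = Y.coords[Y.valid]
        assert v.min() >= lo and v.max() < hi


class TestHeatmap:
    def test_one_hot_row_lights_one_cell(self):
        S = np.zeros((4, 64))
        S[1, 10] = 1.0
        hm = similarity_heatmap(S, 1, 8, 64)
        assert hm.shape == (64, 64)
        iy, ix = divmod(10, 8)
        assert hm.pixels[iy * 8 + 4, ix * 8 + 4] == 1.0
        assert hm.pixels.sum() == pytest.approx(64.0)  # one cell of 8x8 ones

    def test_row_sums_to_one_before_upsampling(self, rng):
        S = rng.random((4, 64))
        S /= S.sum(axis=1, keepdims=True)
        hm = similarity_heatmap(S, 2, 8, 64)
        assert hm.pixels[::8, ::8].sum() == pytest.approx(1.0)

    def test_argmax_cell_center_matches_one_hot_soft_argmax(self, rng):
        cfg = ModelConfig(image_size=64, patch_size=8, embed_dim=16, n_blocks=0)
        net = HomologousPointNet(cfg, seed=0)
        S = rng.random((4, 64))
        S /= S.sum(axis=1, keepdims=True)
        hm = similarity_heatmap(S, 0, 8, 64)
        j = int(np.argmax(S[0]))
        one_hot = np.zeros((1, 64))
        one_hot[0, j] = 1.0
        center = net.soft_argmax(Tensor(one_hot)).data[0]
        cell = np.unravel_index(np.argmax(hm.pixels[4::8, 4::8]), (8, 8))
        assert np.allclose([cell[0] * 8 + 4, cell[1] * 8 + 4], center)

    def test_uniform_row_constant_image(self):
        S = np.full((2, 64), 1 / 64)
        hm = similarity_heatmap(S, 0, 8, 64)
        assert np.ptp(hm.pixels) == 0

    def test_invalid_row_raises(self):
        with pytest.raises(IndexError):
            similarity_heatmap(np.zeros((2, 64)), 5, 8, 64)


class TestParametersAndCheckpoints:
    def test_count_matches_hand_tally_tiny(self):
        cfg = ModelConfig(image_size=64, patch_size=8, embed_dim=16, n_blocks=1, n_heads=2)
        d, q, N = 16, 2, 64
        patch = (4 * 1 * 64 + 64) + (4 * 64 * 64 + 64) + (q * q * 64 * d + d)
        pos = N * d
        attn = 4 * (d * d + d)
        ln = 2 * 2 * d
        ffn = (d * 4 * d + 4 * d) + (9 * 4 * d + 4 * d) + (4 * d * d + d)
        per_branch = patch + pos + attn + ln + ffn
        assert count_parameters(cfg) == 2 * per_branch

    def test_instance_count_equals_analytic(self, tiny_net):
        assert tiny_net.n_parameters() == count_parameters(tiny_net.config)

    def test_checkpoint_round_trip(self, tmp_path, tiny_net, rng):
        path = tmp_path / "w.npz"
        tiny_net.save(path)
        back = HomologousPointNet.load(path)
        assert back.config == tiny_net.config
        M, F = rng.random((64, 64)), rng.random((64, 64))
        X = pad_points(PointSet(rng.uniform(0, 63, (3, 2))), tiny_net.config.L)
        assert np.array_equal(
            back.predict_points(M, F, X).coords, tiny_net.predict_points(M, F, X).coords
        )

    def test_mismatched_state_rejected(self, tiny_net):
        state = tiny_net.state_dict()
        state.pop(next(iter(state)))
        with pytest.raises(ValueError):
            tiny_net.load_state_dict(state)
        bad = tiny_net.state_dict()
        k = next(iter(bad))
        bad[k] = np.zeros((1, 1))
        with pytest.raises(ValueError, match="shape"):
            tiny_net.load_state_dict(bad)

    def test_branch_param_names_disjoint(self, tiny_net):
        a = set(tiny_net.branch_param_names("histology"))
        b = set(tiny_net.branch_param_names("mr"))
        assert not (a & b)
        assert a | b == set(tiny_net.params)
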