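"""Transformer components: patching, embedding, positional encoding,
attention, heads, full forward pass and exact gradients."""

import numpy as np
import pytest

from fetalvit import model as M
from fetalvit import train as T
from fetalvit.model import ViTConfig
from fetalvit.worked_example import WORKED_EXAMPLE, run_worked_example


class TestPatchify:
    def test_patch_count_224_over_16(self):
        grid = M.patchify(np.zeros((224, 224)), 16)
        assert grid.n == 196

    def test_first_patch_indexing(self):
        img = np.arange(1, 17, dtype=float).reshape(4, 4)
        grid = M.patchify(img, 2)
        np.testing.assert_array_equal(grid.patches[0], [[1, 2], [5, 6]])

    def test_roundtrip_exact(self, rng):
        img = rng.random((32, 32))
        np.testing.assert_array_equal(M.unpatchify(M.patchify(img, 8)), img)

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError):
            M.patchify(np.zeros((30, 30)), 16)


class TestEmbedding:
    def test_identity_projection_returns_flattened_patches(self, rng):
        grid = M.patchify(rng.random((8, 8)), 4)
        out = M.embed_patches(grid, np.eye(16), np.zeros(16))
        np.testing.assert_allclose(out, grid.patches.reshape(4, 16))

    def test_matches_flatten_multiply_oracle(self, rng):
        grid = M.patchify(rng.random((8, 8)), 4)
        proj, bias = rng.normal(size=(16, 6)), rng.normal(size=6)
        out = M.embed_patches(grid, proj, bias)
        assert out.shape == (4, 6)
        for i in range(4):
            expected = grid.patches[i].ravel() @ proj + bias
            np.testing.assert_allclose(out[i], expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        grid = M.patchify(rng.random((8, 8)), 4)
        with pytest.raises(ValueError):
            M.embed_patches(grid, np.eye(9), np.zeros(9))


class TestPositionalEncoding:
    def test_position_zero_and_bounds(self):
        pe = M.positional_encoding(10, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)
        assert np.all(np.abs(pe) <= 1.0)

    def test_rows_pairwise_distinct(self):
        pe = M.positional_encoding(512, 64)
        # brute-force pairwise check via unique rows
        assert len(np.unique(pe.round(12), axis=0)) == 512

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            M.positional_encoding(4, 7)

    def test_2d_variant_distinguishes_rows_and_columns(self):
        pe = M.positional_encoding_2d(4, 4, 16)
        assert len(np.unique(pe.round(12), axis=0)) == 16


def _attention_oracle(eq, ec, wq, wk, wv):
    """Three-line direct evaluation of softmax(QKᵀ/√d_k)·V."""
    q, k, v = eq @ wq, ec @ wk, ec @ wv
    s = q @ k.T / np.sqrt(wq.shape[1])
    w = np.exp(s - s.max(1, keepdims=True))
    w /= w.sum(1, keepdims=True)
    return w @ v, w


class TestAttention:
    def test_single_token_weight_is_one(self, rng):
        e = rng.normal(size=(1, 4))
        wq, wk, wv = (rng.normal(size=(4, 2)) for _ in range(3))
        out, w = M.self_attention(e, wq, wk, wv)
        np.testing.assert_allclose(w, [[1.0]])
        np.testing.assert_allclose(out, e @ wv)

    def test_zero_query_gives_uniform_weights(self, rng):
        e = rng.normal(size=(5, 4))
        wv = rng.normal(size=(4, 2))
        out, w = M.self_attention(e, np.zeros((4, 2)), np.zeros((4, 2)), wv)
        np.testing.assert_allclose(w, 1.0 / 5)
        np.testing.assert_allclose(out, np.tile((e @ wv).mean(0), (5, 1)))

    def test_matches_direct_evaluation_oracle(self, rng):
        e = rng.normal(size=(3, 4))
        wq, wk, wv = (rng.normal(size=(4, 2)) for _ in range(3))
        out, w = M.self_attention(e, wq, wk, wv)
        oracle_out, oracle_w = _attention_oracle(e, e, wq, wk, wv)
        np.testing.assert_allclose(out, oracle_out, atol=1e-10)
        np.testing.assert_allclose(w, oracle_w, atol=1e-10)
        np.testing.assert_allclose(w.sum(1), 1.0, atol=1e-9)

    def test_cross_attention_reduces_to_self_attention(self, rng):
        e = rng.normal(size=(4, 6))
        wq, wk, wv = (rng.normal(size=(6, 3)) for _ in range(3))
        out_s, w_s = M.self_attention(e, wq, wk, wv)
        out_c, w_c = M.cross_attention(e, e, wq, wk, wv)
        np.testing.assert_array_equal(out_s, out_c)
        np.testing.assert_array_equal(w_s, w_c)

    def test_cross_attention_single_context_token(self, rng):
        eq = rng.normal(size=(4, 6))
        ec = rng.normal(size=(1, 6))
        wq, wk, wv = (rng.normal(size=(6, 3)) for _ in range(3))
        out, w = M.cross_attention(eq, ec, wq, wk, wv)
        np.testing.assert_allclose(w, 1.0)
        np.testing.assert_allclose(out, np.tile(ec @ wv, (4, 1)))

    def test_cross_attention_oracle_and_dim_mismatch(self, rng):
        eq, ec = rng.normal(size=(2, 4)), rng.normal(size=(5, 4))
        wq, wk, wv = (rng.normal(size=(4, 2)) for _ in range(3))
        out, _ = M.cross_attention(eq, ec, wq, wk, wv)
        np.testing.assert_allclose(
            out, _attention_oracle(eq, ec, wq, wk, wv)[0], atol=1e-10
        )
        with pytest.raises(ValueError):
            M.cross_attention(rng.normal(size=(2, 3)), ec, wq, wk, wv)

    def test_zero_dk_rejected(self, rng):
        e = rng.normal(size=(3, 4))
        with pytest.raises(ValueError):
            M.self_attention(e, np.zeros((4, 0)), np.zeros((4, 0)), np.zeros((4, 0)))

    def test_batched_multihead_agrees_with_single_head_formula(self, rng):
        """heads=1 in the batched path reproduces the printed equation."""
        e = rng.normal(size=(1, 5, 6))
        wq, wk, wv = (rng.normal(size=(6, 6)) for _ in range(3))
        out, _, _ = M._mha_fwd(e, e, wq, wk, wv, heads=1)
        oracle, _ = _attention_oracle(e[0], e[0], wq, wk, wv)
        np.testing.assert_allclose(out[0], oracle, atol=1e-10)


class TestHeads:
    def test_reference_probabilities(self):
        res = run_worked_example()
        np.testing.assert_allclose(
            np.round(res["class_probs"], 3), [0.273, 0.021, 0.706]
        )

    def test_reference_severity_score(self):
        assert run_worked_example()["severity_score"] == pytest.approx(2.05)

    def test_zero_weights_give_uniform_probabilities(self):
        probs = M.classification_head(np.array([1.0, 2.0]), np.zeros((3, 2)), np.zeros(3))
        np.testing.assert_allclose(probs, 1.0 / 3)

    def test_softmax_shift_invariance(self, rng):
        x = rng.normal(size=4)
        w, b = rng.normal(size=(3, 4)), rng.normal(size=3)
        p1 = M.classification_head(x, w, b)
        p2 = M.classification_head(x, w, b + 10.0)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_severity_affine_oracle(self, rng):
        x, w = rng.normal(size=5), rng.normal(size=5)
        b = float(rng.normal())
        assert M.severity_head(x, w, b) == float(w @ x + b)
        assert M.severity_head(x, np.zeros(5), 0.2) == pytest.approx(0.2)


class TestForward:
    def test_probabilities_sum_to_one(self, tiny_model, rng):
        params, cfg = tiny_model
        out = M.forward(params, rng.random((4, 16, 16)), cfg)
        np.testing.assert_allclose(out.class_probs.sum(1), 1.0, atol=1e-9)
        assert np.all(out.class_probs >= 0)

    def test_attention_rows_stochastic(self, tiny_model, rng):
        params, cfg = tiny_model
        out = M.forward(params, rng.random((2, 16, 16)), cfg)
        assert out.attention_maps  # self-attention layers plus cross block
        for a in out.attention_maps:
            np.testing.assert_allclose(a.sum(-1), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, tiny_config, rng):
        img = rng.random((16, 16))
        out1 = M.forward(M.init_params(tiny_config, seed=3), img, tiny_config)
        out2 = M.forward(M.init_params(tiny_config, seed=3), img, tiny_config)
        np.testing.assert_array_equal(out1.class_probs, out2.class_probs)
        np.testing.assert_array_equal(out1.severity_score, out2.severity_score)

    def test_token_permutation_symmetry_depends_on_positional_encoding(self, rng):
        """Without positional encoding mean-pooled heads are permutation
        invariant; enabling it breaks the symmetry (it carries position)."""
        img = rng.random((16, 16))
        perm = np.random.default_rng(0).permutation(4)
        base = dict(image_size=(16, 16), patch_size=8, embed_dim=8, depth=2,
                    heads=2, num_classes=3)

        def permute_patches(img):
            grid = M.patchify(img, 8)
            pg = M.PatchGrid(8, grid.rows, grid.cols, grid.patches[perm])
            return M.unpatchify(pg)

        for use_pos, should_match in [(False, True), (True, False)]:
            cfg = ViTConfig(**base, use_positional=use_pos)
            params = M.init_params(cfg, seed=11)
            p1 = M.forward(params, img, cfg).class_probs
            p2 = M.forward(params, permute_patches(img), cfg).class_probs
            assert np.allclose(p1, p2, atol=1e-9) == should_match

    def test_wrong_image_shape_rejected(self, tiny_model):
        params, cfg = tiny_model
        with pytest.raises(ValueError):
            M.forward(params, np.zeros((17, 16)), cfg)


class TestGradients:
    @pytest.mark.parametrize("use_cross,use_attn,heads", [
        (True, True, 2), (False, True, 1), (False, False, 2),
    ])
    def test_backward_matches_central_differences(self, use_cross, use_attn, heads):
        """Analytic gradients of the composite loss agree with numerical
        differentiation for every parameter group."""
        cfg = ViTConfig(image_size=(16, 16), patch_size=8, embed_dim=8, depth=2,
                        heads=heads, num_classes=3, use_cross_attention=use_cross,
                        use_self_attention=use_attn)
        params = M.init_params(cfg, seed=1)
        rng = np.random.default_rng(0)
        imgs = rng.random((3, 16, 16))
        y = np.array([0, 2, 1])
        sev = rng.random(3)
        tc = T.TrainConfig(model=cfg, lam=0.7, max_epochs=1)

        def loss_fn():
            out = M.forward(params, imgs, cfg)
            lc = -np.mean(np.log(out.class_probs[np.arange(3), y]))
            ls = np.mean((out.severity_score - sev) ** 2)
            return lc + 0.7 * ls

        _, grads, _ = T._batch_loss_and_grads(params, imgs, y, sev, tc)
        eps = 1e-6
        pick = np.random.default_rng(2)
        for key, g in grads.items():
            p = params[key]
            flat_idx = pick.choice(max(p.size, 1), size=min(4, max(p.size, 1)),
                                   replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape) if p.ndim else ()
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss_fn()
                p[idx] = orig - eps
                lm = loss_fn()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = np.asarray(g)[idx]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), key
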