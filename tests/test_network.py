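"""Attention, encoder, pooling and accounting against independent oracles."""

import numpy as np
import pytest

from ptnfall.autodiff import Tensor
from ptnfall.network import (ModelConfig, PatchTransformer, conv_output_size,
                             count_params, estimate_flops, load_checkpoint,
                             save_checkpoint, self_attention)

RNG = np.random.default_rng(2024)


def _sa_oracle(x, wq, wk, wv, d_k, scale="sqrt"):
    """Element-by-element scalar computation of scaled dot-product attention."""
    q, k, v = x @ wq, x @ wk, x @ wv
    n = x.shape[0]
    denom = np.sqrt(d_k) if scale == "sqrt" else d_k
    out = np.zeros_like(v)
    for i in range(n):
        scores = np.array([sum(q[i, a] * k[j, a] for a in range(q.shape[1]))
                           for j in range(n)]) / denom
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(n):
            out[i] += w[j] * v[j]
    return out


class TestSelfAttention:
    def test_matches_scalar_oracle_on_many_random_instances(self):
        for trial in range(120):
            n = int(RNG.integers(1, 6))
            d = int(RNG.integers(1, 5))
            dk = int(RNG.integers(1, 4))
            x = RNG.normal(size=(n, d))
            wq, wk, wv = (RNG.normal(size=(d, dk)) for _ in range(3))
            scale = "sqrt" if trial % 2 == 0 else "linear"
            out = self_attention(Tensor(x), Tensor(wq), Tensor(wk), Tensor(wv),
                                 dk, scale).data
            assert np.allclose(out, _sa_oracle(x, wq, wk, wv, dk, scale),
                               atol=1e-10)

    def test_single_token_returns_v(self):
        x = RNG.normal(size=(1, 4))
        wq, wk, wv = (RNG.normal(size=(4, 2)) for _ in range(3))
        out = self_attention(Tensor(x), Tensor(wq), Tensor(wk), Tensor(wv), 2)
        assert np.allclose(out.data, x @ wv)

    def test_identical_rows_give_uniform_weights(self):
        x = np.tile(RNG.normal(size=(1, 5)), (4, 1))
        wq, wk, wv = (RNG.normal(size=(5, 3)) for _ in range(3))
        out = self_attention(Tensor(x), Tensor(wq), Tensor(wk), Tensor(wv), 3)
        v = x @ wv
        assert np.allclose(out.data, np.tile(v.mean(axis=0), (4, 1)))

    def test_two_token_hand_computation(self):
        # N=2, d_k=1 worked through by hand
        x = np.array([[1.0], [2.0]])
        wq = wk = wv = np.array([[1.0]])
        out = self_attention(Tensor(x), Tensor(wq), Tensor(wk), Tensor(wv),
                             1, "sqrt").data
        # row 0: scores (1, 2) -> softmax = (e^1, e^2)/Z
        w01 = np.exp(2) / (np.exp(1) + np.exp(2))
        expect0 = (1 - w01) * 1.0 + w01 * 2.0
        w11 = np.exp(4) / (np.exp(2) + np.exp(4))
        expect1 = (1 - w11) * 1.0 + w11 * 2.0
        assert np.allclose(out.ravel(), [expect0, expect1])

    def test_attention_rows_sum_to_one(self):
        for _ in range(25):
            n, d = int(RNG.integers(2, 8)), 6
            x = Tensor(RNG.normal(size=(n, d)))
            scores = ((x @ Tensor(RNG.normal(size=(d, 3))))
                      @ (x @ Tensor(RNG.normal(size=(d, 3)))).swapaxes(-1, -2))
            w = scores.softmax().data
            assert np.all(w >= 0)
            assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_invalid_dk_rejected(self):
        with pytest.raises(ValueError):
            self_attention(Tensor(np.ones((2, 2))), Tensor(np.ones((2, 1))),
                           Tensor(np.ones((2, 1))), Tensor(np.ones((2, 1))), 0)


class TestMultiHead:
    def test_per_head_width(self):
        assert ModelConfig(channels=9, patch_side=20, seq_len=11).d_k == 27
        assert ModelConfig(channels=3, patch_side=10, seq_len=2).d_k == 3

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            ModelConfig(channels=3, patch_side=10, seq_len=2, heads=2)

    def test_single_head_with_identity_output_projection_reduces_to_sa(self):
        cfg = ModelConfig(channels=2, patch_side=6, seq_len=3, heads=1,
                          layers=1, seed=0)
        model = PatchTransformer(cfg)
        msa = model.encoder[0].msa
        msa.w_o.weight.data = np.eye(cfg.d_model)
        msa.w_o.bias.data[:] = 0.0
        x = RNG.normal(size=(1, 3, cfg.d_model))
        out = msa(Tensor(x)).data[0]
        oracle = _sa_oracle(x[0], msa.w_q.data[0], msa.w_k.data[0],
                            msa.w_v.data[0], cfg.d_k)
        assert np.allclose(out, oracle, atol=1e-10)


class TestEncoder:
    def test_zeroed_residual_branches_make_identity(self, tiny_model):
        for layer in tiny_model.encoder:
            layer.msa.w_o.weight.data[:] = 0.0
            layer.msa.w_o.bias.data[:] = 0.0
            layer.fc2.weight.data[:] = 0.0
            layer.fc2.bias.data[:] = 0.0
        x = RNG.normal(size=(2, 2, 9))
        t = Tensor(x)
        for layer in tiny_model.encoder:
            t = layer(t)
        assert np.allclose(t.data, x)

    @pytest.mark.parametrize("n,d", [(1, 9), (11, 81)])
    def test_shape_preserved(self, n, d):
        c = int(np.sqrt(d))
        cfg = ModelConfig(channels=c, patch_side=10, seq_len=n, layers=1, seed=0)
        layer = PatchTransformer(cfg).encoder[0]
        x = RNG.normal(size=(1, n, d))
        assert layer(Tensor(x)).shape == (1, n, d)

    def test_staged_oracle_for_one_layer(self):
        """LN -> MSA -> residual -> LN -> MLP -> residual, stage by stage."""
        cfg = ModelConfig(channels=3, patch_side=10, seq_len=2, layers=1,
                          seed=5)
        layer = PatchTransformer(cfg).encoder[0]
        x = np.random.default_rng(6).normal(size=(1, 2, 9))

        def ln(v, gamma, beta, eps=1e-5):
            mu = v.mean(-1, keepdims=True)
            var = v.var(-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * gamma + beta

        h = ln(x, layer.ln1.gamma.data, layer.ln1.beta.data)
        heads = [
            _sa_oracle(h[0], layer.msa.w_q.data[i], layer.msa.w_k.data[i],
                       layer.msa.w_v.data[i], cfg.d_k)
            for i in range(cfg.heads)
        ]
        msa_out = (np.concatenate(heads, axis=-1) @ layer.msa.w_o.weight.data
                   + layer.msa.w_o.bias.data)
        x1 = msa_out[None] + x
        h2 = ln(x1, layer.ln2.gamma.data, layer.ln2.beta.data)
        z = h2 @ layer.fc1.weight.data + layer.fc1.bias.data
        z = 0.5 * z * (1 + np.tanh(np.sqrt(2 / np.pi) * (z + 0.044715 * z**3)))
        expected = z @ layer.fc2.weight.data + layer.fc2.bias.data + x1
        assert np.allclose(layer(Tensor(x)).data, expected, atol=1e-9)


class TestForward:
    def test_conv_embed_spatial_sizes(self):
        assert conv_output_size(20) == 10 and conv_output_size(10) == 5
        assert conv_output_size(10) == 5 and conv_output_size(5) == 3

    @pytest.mark.parametrize("n_seq", [1, 5, 11])
    def test_embedding_preserves_sequence_length(self, n_seq):
        cfg = ModelConfig(channels=3, patch_side=10, seq_len=n_seq, layers=1,
                          seed=0)
        model = PatchTransformer(cfg)
        blocks = RNG.normal(size=(2, n_seq, 10, 10, 3))
        assert model.embed(blocks).shape == (2, n_seq, 9)
        fmap = model.feature_map(blocks[0])
        assert fmap.shape == (9, n_seq)
        assert np.isfinite(fmap).all()

    def test_output_is_simplex(self, tiny_model):
        probs = tiny_model.predict_proba(RNG.normal(size=(3, 2, 10, 10, 3)))
        assert probs.shape == (3, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_gap_of_constant_tokens_returns_the_token(self):
        token = RNG.normal(size=9)
        x = Tensor(np.tile(token, (1, 7, 1)))
        assert np.allclose(x.mean(axis=1).data[0], token)

    def test_gap_matches_brute_force_mean(self):
        for _ in range(100):
            y = RNG.normal(size=(11, 81))
            pooled = Tensor(y[None]).mean(axis=1).data[0]
            brute = np.array([sum(y[i, j] for i in range(11)) / 11.0
                              for j in range(81)])
            assert np.allclose(pooled, brute, atol=1e-12)

    def test_sequence_length_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="sequence length"):
            tiny_model.forward(RNG.normal(size=(1, 3, 10, 10, 3)))

    def test_forward_is_deterministic(self, tiny_model):
        x = RNG.normal(size=(2, 2, 10, 10, 3))
        a = tiny_model.forward(x).data
        b = tiny_model.forward(x).data
        assert np.array_equal(a, b)

    def test_joint_token_and_positional_permutation(self):
        cfg = ModelConfig(channels=3, patch_side=10, seq_len=5, layers=2,
                          seed=3)
        model = PatchTransformer(cfg)
        x = RNG.normal(size=(1, 5, 10, 10, 3))
        base = model.forward(x).data
        perm = np.array([3, 0, 4, 1, 2])
        model.pos.data = model.pos.data[perm]
        permuted = model.forward(x[:, perm]).data
        # GAP is symmetric, so jointly permuting tokens and E_pos rows
        # leaves the pooled prediction unchanged
        assert np.allclose(permuted, base, atol=1e-9)

    def test_small_patch_requires_flatten_embedder(self):
        with pytest.raises(ValueError, match="patch_side"):
            ModelConfig(channels=3, patch_side=3, seq_len=2)
        cfg = ModelConfig(channels=3, patch_side=3, seq_len=2,
                          local_features=False)
        assert PatchTransformer(cfg).predict_proba(
            RNG.normal(size=(1, 2, 3, 3, 3))).shape == (1, 2)


def _expected_params(cfg: ModelConfig) -> int:
    """Closed-form hand count of every weight tensor."""
    d, c, n = cfg.d_model, cfg.channels, cfg.patch_side
    total = 0
    if cfg.local_features:
        cm = cfg.conv_channel_factor * c
        total += (9 * c) * cm + cm            # conv1
        total += (9 * cm) * cm + cm           # conv2
        s2 = conv_output_size(conv_output_size(n))
        total += (s2 * s2 * cm) * d + d       # projection
    else:
        total += (n * n * c) * d + d
    total += cfg.seq_len * d                  # positional table
    per_layer = (
        3 * cfg.heads * d * cfg.d_k           # W_Q, W_K, W_V
        + cfg.heads * cfg.d_k * d + d         # W_O
        + 4 * d                               # two layer norms
        + d * cfg.mlp_hidden + cfg.mlp_hidden
        + cfg.mlp_hidden * d + d
    )
    total += cfg.layers * per_layer
    total += 2 * d                            # final layer norm
    total += d * cfg.num_classes + cfg.num_classes
    return total


class TestAccounting:
    def test_param_count_matches_hand_enumeration_over_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            c = int(rng.choice([2, 3, 4]))
            cfg = ModelConfig(
                channels=c,
                patch_side=int(rng.integers(4, 12)),
                seq_len=int(rng.integers(1, 8)),
                heads=c,
                layers=int(rng.integers(1, 4)),
                local_features=bool(rng.integers(0, 2)),
                seed=0,
            )
            assert count_params(PatchTransformer(cfg)) == _expected_params(cfg)

    def test_single_linear_map_hand_count(self):
        # a 9 -> 2 linear map with bias holds 20 parameters
        cfg = ModelConfig(channels=3, patch_side=10, seq_len=2, seed=0)
        model = PatchTransformer(cfg)
        head = sum(p.data.size for _, p in model.head.named_parameters("head"))
        assert head == 9 * 2 + 2

    def test_param_count_invariant_to_batch_size(self, tiny_model):
        before = count_params(tiny_model)
        tiny_model.forward(RNG.normal(size=(5, 2, 10, 10, 3)))
        assert count_params(tiny_model) == before

    def test_flops_strictly_increase_with_sequence_length(self):
        counts = []
        for n_seq in (2, 4, 8):
            cfg = ModelConfig(channels=3, patch_side=10, seq_len=n_seq, seed=0)
            counts.append(estimate_flops(PatchTransformer(cfg)))
        assert counts[0] < counts[1] < counts[2]
        # the attention-score term grows as N^2, so flops are super-linear:
        # the increment over 4->8 exceeds twice the increment over 2->4
        assert counts[2] - counts[1] > 2 * (counts[1] - counts[0])

    def test_conv_embedder_is_smaller_than_direct_projection(self):
        # the stacked small convolutions shrink the patch before the token
        # projection, so the conv embedder carries fewer parameters than a
        # dense flatten-and-project of the full n*n*C patch
        cfg = ModelConfig(channels=3, patch_side=10, seq_len=2, seed=0)
        conv = PatchTransformer(cfg)
        flat = conv.ablate_local_features(False)
        assert count_params(conv) < count_params(flat)
        x = RNG.normal(size=(2, 2, 10, 10, 3))
        for m in (conv, flat):
            p = m.predict_proba(x)
            assert np.allclose(p.sum(axis=1), 1.0)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_model, tmp_path):
        x = RNG.normal(size=(2, 2, 10, 10, 3))
        before = tiny_model.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_model)
        restored = load_checkpoint(path)
        assert np.array_equal(restored.predict_proba(x), before)
        assert restored.config == tiny_model.config
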