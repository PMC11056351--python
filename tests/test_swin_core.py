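"""Window plumbing, masking and attention against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmpmixer.nn import functional as F
from scmpmixer.swin_core import (MASK_NEG, SwinBlockConfig, SwinCycle,
                                 WindowAttention, attention_mask, cyclic_shift,
                                 window_partition, window_reverse)


def _numbered_grid(side, dim=1):
    return np.arange(side * side, dtype=np.float64).reshape(1, side, side, dim)


class TestWindowPartition:
    def test_block_counts_28x28_window7(self, rng):
        g = rng.random((2, 28, 28, 5))
        blocks = window_partition(g, 7)
        assert blocks.shape == (2 * 16, 49, 5)

    def test_single_window_is_rowmajor_identity(self):
        g = _numbered_grid(2)
        blocks = window_partition(g, 2)
        assert blocks.shape == (1, 4, 1)
        np.testing.assert_array_equal(blocks[0, :, 0], [0, 1, 2, 3])

    def test_4x4_window2_against_enumeration_oracle(self):
        # oracle: walk windows top-left to bottom-right, tokens row-major
        g = _numbered_grid(4)
        expected = []
        for wi in range(2):
            for wj in range(2):
                block = [4 * (2 * wi + r) + (2 * wj + c)
                         for r in range(2) for c in range(2)]
                expected.append(block)
        blocks = window_partition(g, 2)
        np.testing.assert_array_equal(blocks[..., 0], expected)
        # frozen values for the first two windows
        np.testing.assert_array_equal(blocks[0, :, 0], [0, 1, 4, 5])
        np.testing.assert_array_equal(blocks[1, :, 0], [2, 3, 6, 7])

    def test_every_token_in_exactly_one_block(self, rng):
        g = _numbered_grid(6)
        blocks = window_partition(g, 3)
        assert sorted(blocks.ravel().tolist()) == list(range(36))

    def test_nondivisible_grid_raises_naming_dims(self):
        with pytest.raises(ValueError, match="5x5"):
            window_partition(np.zeros((1, 5, 5, 2)), 2)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(nh=st.integers(1, 4), nw=st.integers(1, 4),
           window=st.integers(1, 4), b=st.integers(1, 3),
           dim=st.integers(1, 5))
    def test_partition_reverse_roundtrip(self, nh, nw, window, b, dim):
        rng = np.random.default_rng(nh * 1000 + nw * 100 + window * 10 + b)
        g = rng.random((b, nh * window, nw * window, dim))
        blocks = window_partition(g, window)
        np.testing.assert_array_equal(
            window_reverse(blocks, nh * window, nw * window, window), g)

    def test_reverse_single_block_reshapes(self, rng):
        g = rng.random((1, 3, 3, 2))
        blocks = window_partition(g, 3)
        np.testing.assert_array_equal(window_reverse(blocks, 3, 3, 3), g)

    def test_reverse_rejects_inconsistent_shapes(self):
        with pytest.raises(ValueError):
            window_reverse(np.zeros((3, 4, 2)), 4, 4, 2)
        with pytest.raises(ValueError):
            window_reverse(np.zeros((4, 9, 2)), 4, 4, 2)


class TestCyclicShift:
    def test_zero_shift_identity(self, rng):
        g = rng.random((1, 4, 4, 2))
        np.testing.assert_array_equal(cyclic_shift(g, 0, "forward"), g)

    def test_forward_then_reverse_identity(self, rng):
        g = rng.random((2, 6, 6, 3))
        out = cyclic_shift(cyclic_shift(g, 2, "forward"), 2, "reverse")
        np.testing.assert_array_equal(out, g)

    def test_3x3_shift1_against_index_oracle(self):
        g = _numbered_grid(3)
        shifted = cyclic_shift(g, 1, "forward")
        # oracle: forward shift moves token (i, j) to ((i-1) % 3, (j-1) % 3)
        expected = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                expected[(i - 1) % 3, (j - 1) % 3] = g[0, i, j, 0]
        np.testing.assert_array_equal(shifted[0, :, :, 0], expected)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            cyclic_shift(np.zeros((1, 2, 2, 1)), 1, "sideways")


class TestAttentionMask:
    def test_zero_shift_all_zero(self):
        mask = attention_mask(4, 4, 2, 0)
        assert mask.shape == (4, 4, 4)
        assert np.all(mask == 0)

    def test_4x4_window2_shift1_matches_region_labeling_oracle(self):
        window, shift = 2, 1
        # oracle: label each pre-shift region, roll, partition by loops,
        # mask pairs with differing labels
        labels = np.zeros((4, 4), dtype=int)
        region = 0
        for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            for ws in (slice(0, -window), slice(-window, -shift),
                       slice(-shift, None)):
                labels[hs, ws] = region
                region += 1
        expected = np.zeros((4, 4, 4))
        widx = 0
        for wi in range(2):
            for wj in range(2):
                flat = [labels[2 * wi + r, 2 * wj + c]
                        for r in range(2) for c in range(2)]
                for a in range(4):
                    for b in range(4):
                        if flat[a] != flat[b]:
                            expected[widx, a, b] = MASK_NEG
                widx += 1
        np.testing.assert_array_equal(attention_mask(4, 4, window, shift),
                                      expected)

    def test_masked_softmax_all_but_self_gives_self_weight_one(self):
        logits = np.zeros(5)
        mask = np.full(5, MASK_NEG)
        mask[2] = 0.0
        w = F.softmax(logits + mask)
        assert w[2] == pytest.approx(1.0, abs=1e-6)


def _dense_attention_oracle(x, layer, mask=None):
    """Brute-force per-block softmax(QK^T/sqrt(d) + bias + mask)V."""
    nb, t, d = x.shape
    h, dh = layer.heads, layer.head_dim
    out = np.zeros_like(x)
    for bi in range(nb):
        qkv = x[bi] @ layer.qkv.weight.data + layer.qkv.bias.data
        q, k, v = qkv[:, :d], qkv[:, d:2 * d], qkv[:, 2 * d:]
        ctx = np.zeros((t, d))
        for head in range(h):
            sl = slice(head * dh, (head + 1) * dh)
            logits = q[:, sl] @ k[:, sl].T / np.sqrt(dh)
            if layer.use_relative_bias:
                logits = logits + layer.rel_table.data[layer.rel_index][:, :, head]
            if mask is not None:
                logits = logits + mask[bi % mask.shape[0]]
            weights = np.exp(logits - logits.max(axis=1, keepdims=True))
            weights /= weights.sum(axis=1, keepdims=True)
            ctx[:, sl] = weights @ v[:, sl]
        out[bi] = ctx @ layer.proj.weight.data + layer.proj.bias.data
    return out


class TestWindowAttention:
    @pytest.mark.parametrize("window,use_bias", [(2, False), (2, True),
                                                 (3, False), (3, True)])
    def test_matches_dense_oracle_small_blocks(self, rng, window, use_bias):
        dim = 8
        layer = WindowAttention(dim, heads=2, window=window,
                                rng=np.random.default_rng(3),
                                use_relative_bias=use_bias)
        x = rng.random((4, window * window, dim)).astype(np.float32)
        mask = attention_mask(2 * window, 2 * window, window, 1)
        for m in (None, mask):
            np.testing.assert_allclose(
                layer.forward(x, m), _dense_attention_oracle(x, layer, m),
                atol=1e-5)

    def test_two_tokens_hand_set_weights_closed_form(self):
        # 1 head, dim 2, identity projections: softmax(QK^T/sqrt(2)) V
        layer = WindowAttention(2, heads=1, window=1,
                                rng=np.random.default_rng(0),
                                use_relative_bias=False)
        eye = np.eye(2, dtype=np.float32)
        layer.qkv.weight.data[...] = np.concatenate([eye, eye, eye], axis=1)
        layer.qkv.bias.data[...] = 0
        layer.proj.weight.data[...] = eye
        layer.proj.bias.data[...] = 0
        x = np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32)
        s = 1.0 / np.sqrt(2.0)
        logits = (x[0] @ x[0].T) * s
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        expected = (e / e.sum(axis=1, keepdims=True)) @ x[0]
        np.testing.assert_allclose(layer.forward(x), expected[None], atol=1e-6)

    def test_single_token_block_is_value_projection(self, rng):
        dim = 4
        layer = WindowAttention(dim, heads=2, window=1,
                                rng=np.random.default_rng(1),
                                use_relative_bias=False)
        x = rng.random((3, 1, dim)).astype(np.float32)
        qkv = x @ layer.qkv.weight.data + layer.qkv.bias.data
        v = qkv[..., 2 * dim:]
        expected = v @ layer.proj.weight.data + layer.proj.bias.data
        np.testing.assert_allclose(layer.forward(x), expected, atol=1e-6)

    def test_permutation_equivariance_without_bias(self, rng):
        layer = WindowAttention(6, heads=3, window=2,
                                rng=np.random.default_rng(2),
                                use_relative_bias=False)
        x = rng.random((1, 4, 6)).astype(np.float32)
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_allclose(layer.forward(x[:, perm]),
                                   layer.forward(x)[:, perm], atol=1e-5)

    def test_attention_rows_sum_to_one_over_unmasked_keys(self, rng):
        # softmax over additively masked logits: full mass on unmasked keys
        logits = rng.normal(size=(4, 9, 9))
        mask = attention_mask(6, 6, 3, 1)
        w = F.softmax(logits + mask, axis=-1)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-5)
        assert w[mask < 0].max() < 1e-6

    def test_nonfinite_input_rejected(self):
        layer = WindowAttention(4, heads=1, window=2,
                                rng=np.random.default_rng(0))
        bad = np.full((1, 4, 4), np.nan, dtype=np.float32)
        with pytest.raises(ValueError, match="non-finite"):
            layer.forward(bad)


class TestSwinCycle:
    def _zero_residual_branches(self, cycle):
        for stage in (cycle.wmsa, cycle.swmsa):
            stage.attn.proj.weight.data[...] = 0
            stage.attn.proj.bias.data[...] = 0
        for mlp in (cycle.mlp1, cycle.mlp2):
            mlp.net.layers[3].weight.data[...] = 0
            mlp.net.layers[3].bias.data[...] = 0

    def test_zeroed_branch_weights_is_identity(self, rng):
        cfg = SwinBlockConfig(window=2, shift=1, heads=2, mlp_dim=8,
                              dropout_rate=0.0)
        cycle = SwinCycle(4, 4, 4, cfg, np.random.default_rng(0))
        self._zero_residual_branches(cycle)
        g = rng.random((2, 4, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(cycle.forward(g), g, atol=1e-6)

    @pytest.mark.parametrize("side", [28, 14])
    def test_shape_preserving_on_default_grids(self, rng, side):
        cfg = SwinBlockConfig(window=7, shift=3, heads=4, mlp_dim=256,
                              dropout_rate=0.0)
        cycle = SwinCycle(256, side, side, cfg, np.random.default_rng(0))
        g = rng.random((1, side, side, 256)).astype(np.float32)
        assert cycle.forward(g).shape == g.shape

    def test_deterministic_with_zero_dropout(self, rng):
        cfg = SwinBlockConfig(window=2, shift=1, heads=2, mlp_dim=8,
                              dropout_rate=0.0)
        cycle = SwinCycle(4, 4, 4, cfg, np.random.default_rng(0))
        g = rng.random((1, 4, 4, 4)).astype(np.float32)
        a, b = cycle.forward(g), cycle.forward(g)
        assert np.array_equal(a, b)

    def test_window_must_divide_grid(self):
        cfg = SwinBlockConfig(window=3, shift=1, heads=2, mlp_dim=8)
        with pytest.raises(ValueError, match="divide"):
            SwinCycle(4, 4, 4, cfg, np.random.default_rng(0))
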