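"""Transformer encoder: positional encoding closed forms, attention
normalization, hand-computed oracles and the single-tower ablation forward."""

import numpy as np
import pytest

import surgphase as sp
from surgphase import nn
from surgphase.encoders import (
    EncoderConfig,
    MultiHeadSelfAttention,
    TransformerEncoder,
    attention_mask,
    masked_mean,
)
from surgphase.exceptions import ConfigurationError


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        pe = sp.positional_encoding(4, 8)
        np.testing.assert_allclose(pe[0], [0, 1, 0, 1, 0, 1, 0, 1])

    def test_closed_form_entry(self):
        pe = sp.positional_encoding(2, 4)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))
        assert pe[1, 1] == pytest.approx(np.cos(1.0))
        assert pe[1, 2] == pytest.approx(np.sin(1.0 / 100.0))

    def test_bounded_by_unit_interval(self):
        pe = sp.positional_encoding(50, 16)
        assert np.abs(pe).max() <= 1.0

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            sp.positional_encoding(3, 7)


class TestSelfAttention:
    def test_single_position_attention_is_identity(self):
        mha = MultiHeadSelfAttention(4, 2, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 1, 4))
        attn = mha.attention_weights(x)
        np.testing.assert_allclose(attn, np.ones((1, 2, 1, 1)))

    def test_rows_sum_to_one(self):
        mha = MultiHeadSelfAttention(8, 4, np.random.default_rng(2))
        x = np.random.default_rng(3).normal(size=(2, 5, 8))
        attn = mha.attention_weights(x)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-12)

    def test_identical_rows_give_identical_outputs(self):
        mha = MultiHeadSelfAttention(6, 3, np.random.default_rng(4))
        row = np.random.default_rng(5).normal(size=6)
        x = np.tile(row, (1, 4, 1))
        out = mha(nn.constant(x)).data[0]
        np.testing.assert_allclose(out, np.tile(out[0], (4, 1)), atol=1e-12)

    def test_against_direct_single_head_evaluation(self):
        """The batched multi-head path must equal a straight-line
        single-head computation with the same weights."""
        mha = MultiHeadSelfAttention(2, 1, np.random.default_rng(6))
        x = np.array([[1.0, 0.5], [-1.0, 2.0]])
        out = mha(nn.constant(x[None])).data[0]

        wq, bq = mha.wq.w.data, mha.wq.b.data
        wk, bk = mha.wk.w.data, mha.wk.b.data
        wv, bv = mha.wv.w.data, mha.wv.b.data
        wo, bo = mha.wo.w.data, mha.wo.b.data
        q, k, v = x @ wq + bq, x @ wk + bk, x @ wv + bv
        scores = q @ k.T / np.sqrt(2.0)
        a = np.exp(scores - scores.max(axis=1, keepdims=True))
        a /= a.sum(axis=1, keepdims=True)
        expected = (a @ v) @ wo + bo
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_padding_mask_blocks_attention_to_padded_keys(self):
        mha = MultiHeadSelfAttention(4, 2, np.random.default_rng(7))
        x = np.random.default_rng(8).normal(size=(1, 5, 4))
        attn = mha.attention_weights(x, attention_mask(np.array([3]), 5))
        np.testing.assert_allclose(attn[..., 3:], 0.0, atol=1e-30)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ConfigurationError):
            MultiHeadSelfAttention(6, 4, np.random.default_rng(0))


class TestEncoder:
    def test_encode_deterministic_and_pooled_is_mean(self):
        enc = TransformerEncoder(EncoderConfig.desk_preset(seed=0))
        seq = np.random.default_rng(9).normal(size=(5, 32))
        o1, o2 = enc.encode(seq), enc.encode(seq)
        np.testing.assert_array_equal(o1.hidden_states, o2.hidden_states)
        np.testing.assert_allclose(
            o1.pooled, o1.hidden_states.mean(axis=0), atol=1e-12
        )

    def test_zeroed_block_outputs_reduce_to_layer_norm_of_input(self):
        """With the attention and FFN output projections zeroed the residual
        path carries LN(LN(x + positional encoding))."""
        enc = TransformerEncoder(EncoderConfig.desk_preset(seed=1, n_layers=1))
        blk = enc.blocks[0]
        for lin in (blk.attn.wo, blk.fc2):
            lin.w.data[:] = 0.0
            lin.b.data[:] = 0.0
        seq = np.random.default_rng(10).normal(size=(4, 32))
        out = enc.encode(seq).hidden_states

        def ln(m, eps=1e-5):
            mu = m.mean(axis=-1, keepdims=True)
            var = ((m - mu) ** 2).mean(axis=-1, keepdims=True)
            return (m - mu) / np.sqrt(var + eps)

        expected = ln(ln(seq + sp.positional_encoding(4, 32)))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_non_finite_input_rejected(self):
        enc = TransformerEncoder(EncoderConfig.desk_preset(seed=2))
        seq = np.full((3, 32), np.nan)
        with pytest.raises(FloatingPointError):
            enc.encode(seq)

    def test_outputs_stay_finite_over_many_seeded_inputs(self):
        enc = TransformerEncoder(
            EncoderConfig.desk_preset(seed=3, n_layers=1, d_model=8,
                                      n_heads=2, d_ff=16)
        )
        rng = np.random.default_rng(11)
        for _ in range(1000):
            out = enc.encode(rng.normal(size=(3, 8), scale=5.0))
            assert np.isfinite(out.hidden_states).all()

    def test_dimension_mismatch_rejected(self):
        enc = TransformerEncoder(EncoderConfig.desk_preset(seed=4))
        with pytest.raises(ConfigurationError):
            enc.encode(np.zeros((3, 16)))


class TestSingleTowerForward:
    def test_sequences_concatenate_image_first(self):
        enc = TransformerEncoder(EncoderConfig.desk_preset(seed=5))
        img = np.random.default_rng(12).normal(size=(3, 32))
        txt = np.random.default_rng(13).normal(size=(2, 32))
        pooled = sp.single_tower_forward(img, txt, enc)
        expected = enc.encode(np.concatenate([img, txt], axis=0)).pooled
        np.testing.assert_array_equal(pooled, expected)

    def test_dim_mismatch_rejected(self):
        enc = TransformerEncoder(EncoderConfig.desk_preset(seed=6))
        with pytest.raises(ConfigurationError):
            sp.single_tower_forward(np.zeros((3, 32)), np.zeros((2, 16)), enc)

    def test_masked_mean_matches_unpadded_mean(self):
        h = nn.constant(np.random.default_rng(14).normal(size=(2, 4, 3)))
        lengths = np.array([2, 4])
        out = masked_mean(h, lengths).data
        np.testing.assert_allclose(out[0], h.data[0, :2].mean(axis=0))
        np.testing.assert_allclose(out[1], h.data[1].mean(axis=0))
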