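"""Transformer primitives against hand and brute-force oracles."""

import math

import numpy as np
import pytest

from mvgat.autodiff import Tensor
from mvgat.transformer import (FeedForward, LayerNorm, MultiHeadAttention,
                               TransformerEncoderBlock, scaled_dot_attention)
from mvgat.views import ValidationError


# -------------------------------------------------------- scaled dot product
def test_single_token_returns_value_exactly(rng):
    q = rng.standard_normal((1, 4))
    k = rng.standard_normal((1, 4))
    v = rng.standard_normal((1, 4))
    np.testing.assert_array_equal(scaled_dot_attention(q, k, v), v)


def test_identical_keys_average_values():
    q = np.array([[1.0, 2.0]])
    k = np.array([[0.3, -0.7], [0.3, -0.7]])
    v = np.array([[1.0, 0.0], [0.0, 2.0]])
    np.testing.assert_allclose(scaled_dot_attention(q, k, v),
                               [[0.5, 1.0]], atol=1e-12)


def test_integer_case_matches_scalar_enumeration():
    """2x2 integer Q, K, V, d_k = 2: exp/normalize by hand."""
    Q = np.array([[1.0, 0.0], [0.0, 2.0]])
    K = np.array([[1.0, 1.0], [2.0, 0.0]])
    V = np.array([[1.0, 2.0], [3.0, 4.0]])
    scale = 1.0 / math.sqrt(2.0)
    expected = np.zeros((2, 2))
    for i in range(2):
        scores = [sum(Q[i][d] * K[j][d] for d in range(2)) * scale
                  for j in range(2)]
        m = max(scores)
        w = [math.exp(s - m) for s in scores]
        tot = sum(w)
        for j in range(2):
            expected[i] += (w[j] / tot) * V[j]
    np.testing.assert_allclose(scaled_dot_attention(Q, K, V), expected,
                               atol=1e-12)


def test_attention_weights_rows_sum_to_one(rng):
    """Outputs are convex combinations: with V = identity the implicit
    weight matrix is recovered and its rows sum to 1."""
    q = rng.standard_normal((5, 3)) * 4
    k = rng.standard_normal((6, 3)) * 4
    weights = scaled_dot_attention(q, k, np.eye(6)[:, :6])
    np.testing.assert_allclose(weights.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(weights >= 0)


def test_dk_mismatch_raises(rng):
    with pytest.raises(ValidationError, match="width"):
        scaled_dot_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 4)))


# -------------------------------------------------------------- multi-head
def test_single_head_identity_projections_reduce_to_scaled_dot(rng):
    mha = MultiHeadAttention(rng, 4, 1)
    for lin in (mha.W_q, mha.W_k, mha.W_v, mha.W_o):
        lin.W.data = np.eye(4)
    x = rng.standard_normal((3, 4))
    y = rng.standard_normal((5, 4))
    np.testing.assert_allclose(mha(Tensor(x), Tensor(y)).data,
                               scaled_dot_attention(x, y, y), atol=1e-12)


def test_zero_output_projection_gives_zeros(rng):
    mha = MultiHeadAttention(rng, 6, 2)
    mha.W_o.W.data = np.zeros((6, 6))
    out = mha(Tensor(rng.standard_normal((4, 6))),
              Tensor(rng.standard_normal((4, 6)))).data
    assert out.shape == (4, 6)
    np.testing.assert_array_equal(out, 0.0)


def test_two_heads_match_per_head_oracle(rng):
    """Head-by-head brute force: slice projections, run scaled-dot per
    head, concat, project."""
    d, h = 6, 2
    mha = MultiHeadAttention(rng, d, h)
    x = rng.standard_normal((3, d))
    y = rng.standard_normal((4, d))
    dk = d // h
    heads = []
    for i in range(h):
        sl = slice(i * dk, (i + 1) * dk)
        qi = x @ mha.W_q.W.data[:, sl]
        ki = y @ mha.W_k.W.data[:, sl]
        vi = y @ mha.W_v.W.data[:, sl]
        heads.append(scaled_dot_attention(qi, ki, vi))
    expected = np.concatenate(heads, axis=1) @ mha.W_o.W.data
    np.testing.assert_allclose(mha(Tensor(x), Tensor(y)).data, expected,
                               atol=1e-10)


def test_heads_must_divide_width(rng):
    with pytest.raises(ValidationError, match="divide"):
        MultiHeadAttention(rng, 7, 2)


# --------------------------------------------------------------------- FFN
def test_ffn_saturated_relu_yields_bias(rng):
    ffn = FeedForward(rng, 2, 3)
    ffn.lin1.W.data = -np.ones((2, 3))
    ffn.lin1.b.data = np.array([-1.0, -2.0, -3.0])
    x = np.abs(rng.standard_normal((4, 2)))  # xW1 + b1 <= 0 elementwise
    out = ffn(Tensor(x)).data
    np.testing.assert_allclose(out, np.broadcast_to(ffn.lin2.b.data, (4, 2)))


def test_ffn_zero_second_layer_yields_bias(rng):
    ffn = FeedForward(rng, 3, 4)
    ffn.lin2.W.data = np.zeros((4, 3))
    ffn.lin2.b.data = np.array([1.0, -1.0, 2.0])
    out = ffn(Tensor(rng.standard_normal((2, 3)))).data
    np.testing.assert_allclose(out, [[1.0, -1.0, 2.0]] * 2)


def test_ffn_integer_hand_evaluation(rng):
    ffn = FeedForward(rng, 2, 3)
    ffn.lin1.W.data = np.array([[1.0, 0.0, -1.0], [2.0, 1.0, 0.0]])
    ffn.lin1.b.data = np.array([0.0, -1.0, 1.0])
    ffn.lin2.W.data = np.array([[1.0, 2.0], [0.0, 1.0], [-1.0, 0.0]])
    ffn.lin2.b.data = np.array([1.0, 1.0])
    x = np.array([[1.0, 2.0]])
    # hidden pre-act: [1*1+2*2, 0+2*1-1, -1+0+1] = [5, 1, 0]; relu same
    # out: [5*1 + 1*0 - 0*1 + 1, 5*2 + 1*1 + 0 + 1] = [6, 12]
    np.testing.assert_allclose(ffn(Tensor(x)).data, [[6.0, 12.0]])


# --------------------------------------------------------------- layer norm
def test_layer_norm_constant_row_returns_beta():
    ln = LayerNorm(4)
    ln.gamma.data = np.full(4, 3.0)
    ln.beta.data = np.array([1.0, 2.0, 3.0, 4.0])
    out = ln(Tensor(np.full((2, 4), 7.0))).data
    np.testing.assert_allclose(out, [[1.0, 2.0, 3.0, 4.0]] * 2)


def test_layer_norm_closed_form_two_entries():
    ln = LayerNorm(2, eps=1e-5)
    out = ln(Tensor(np.array([[1.0, -1.0]]))).data
    expect = 1.0 / math.sqrt(1.0 + 1e-5)
    np.testing.assert_allclose(out, [[expect, -expect]], atol=1e-12)


def test_layer_norm_zero_gamma_returns_beta(rng):
    ln = LayerNorm(5)
    ln.gamma.data = np.zeros(5)
    ln.beta.data = np.arange(5.0)
    out = ln(Tensor(rng.standard_normal((3, 5)))).data
    np.testing.assert_allclose(out, np.tile(np.arange(5.0), (3, 1)))


def test_layer_norm_standardizes_rows(rng):
    ln = LayerNorm(16)
    x = rng.standard_normal((10, 16)) * 5 + 2
    out = ln(Tensor(x)).data
    assert np.all(np.abs(out.mean(axis=-1)) < 1e-5)
    np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-3)


# ------------------------------------------------------------ encoder block
def zero_block(block: TransformerEncoderBlock):
    block.mha.W_o.W.data[:] = 0.0
    block.mlp.lin2.W.data[:] = 0.0
    block.mlp.lin2.b.data[:] = 0.0
    return block


def test_zeroed_block_is_identity(rng):
    block = zero_block(TransformerEncoderBlock(rng, 8, 2))
    x = rng.standard_normal((5, 8))
    np.testing.assert_array_equal(block(Tensor(x)).data, x)


@pytest.mark.parametrize("s", [1, 3, 9])
def test_block_preserves_shape(rng, s):
    block = TransformerEncoderBlock(rng, 8, 4)
    x = rng.standard_normal((s, 8))
    assert block(Tensor(x)).data.shape == (s, 8)


def test_block_matches_component_pipeline(rng):
    """The block equals LN -> MHA -> residual -> LN -> FFN -> residual
    composed from its own sub-modules."""
    block = TransformerEncoderBlock(rng, 6, 2)
    x = rng.standard_normal((4, 6))
    n1 = block.ln_attn(Tensor(x)).data
    r1 = x + block.mha(Tensor(n1), Tensor(n1)).data
    expected = r1 + block.mlp(block.ln_mlp(Tensor(r1))).data
    np.testing.assert_allclose(block(Tensor(x)).data, expected, atol=1e-12)


def test_block_token_permutation_equivariance(rng):
    block = TransformerEncoderBlock(rng, 8, 2)
    x = rng.standard_normal((6, 8))
    perm = rng.permutation(6)
    out = block(Tensor(x)).data
    out_p = block(Tensor(x[perm])).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)
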