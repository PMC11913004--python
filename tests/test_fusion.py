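"""Cross-view block, view fold, and fusion head."""

import numpy as np
import pytest

from mvgat.autodiff import Tensor
from mvgat.fusion import (CrossViewBlock, FusionHead, fuse_and_classify,
                          cross_view_step, retained_outputs, stack_views)
from mvgat.views import ValidationError


def zeroed(block: CrossViewBlock) -> CrossViewBlock:
    block.block.mha.W_o.W.data[:] = 0.0
    block.block.mlp.lin2.W.data[:] = 0.0
    block.block.mlp.lin2.b.data[:] = 0.0
    return block


def test_zeroed_cross_block_passes_first_input(rng):
    block = zeroed(CrossViewBlock(rng, 6, 2))
    x1 = rng.standard_normal((4, 6))
    x2 = rng.standard_normal((7, 6))
    np.testing.assert_array_equal(cross_view_step(Tensor(x1), Tensor(x2),
                                              block).data, x1)


def test_equal_inputs_coincide_with_encoder_block(rng):
    """With the two views equal, the cross block is the self-attention
    encoder block under shared parameters."""
    block = CrossViewBlock(rng, 8, 2)
    x = rng.standard_normal((5, 8))
    cross = cross_view_step(Tensor(x), Tensor(x), block).data
    self_att = block.block(Tensor(x)).data
    np.testing.assert_allclose(cross, self_att, atol=1e-12)


def test_cross_block_matches_stage_oracle(rng):
    """LN both inputs, q from x1 / k,v from x2, residual, MLP, residual —
    composed stage by stage from the sub-modules."""
    block = CrossViewBlock(rng, 6, 3)
    inner = block.block
    x1 = rng.standard_normal((3, 6))
    x2 = rng.standard_normal((5, 6))
    n1 = inner.ln_attn(Tensor(x1)).data
    n2 = inner.ln_attn(Tensor(x2)).data
    r1 = x1 + inner.mha(Tensor(n1), Tensor(n2)).data
    expected = r1 + inner.mlp(inner.ln_mlp(Tensor(r1))).data
    np.testing.assert_allclose(cross_view_step(Tensor(x1), Tensor(x2),
                                           block).data, expected, atol=1e-12)


def test_cross_block_output_keeps_query_token_count(rng):
    block = CrossViewBlock(rng, 4, 2)
    out = cross_view_step(Tensor(np.ones((3, 4))),
                      Tensor(np.ones((9, 4))), block)
    assert out.data.shape == (3, 4)


def test_width_mismatch_raises(rng):
    block = CrossViewBlock(rng, 4, 2)
    with pytest.raises(ValidationError, match="width"):
        cross_view_step(Tensor(np.ones((3, 4))), Tensor(np.ones((3, 6))), block)


def test_invariant_to_kv_token_permutation(rng):
    """Permuting the second view's tokens permutes keys and values
    consistently, leaving the convex value mixture unchanged."""
    block = CrossViewBlock(rng, 8, 2)
    x1 = rng.standard_normal((4, 8))
    x2 = rng.standard_normal((6, 8))
    perm = rng.permutation(6)
    out = cross_view_step(Tensor(x1), Tensor(x2), block).data
    out_p = cross_view_step(Tensor(x1), Tensor(x2[perm]), block).data
    np.testing.assert_allclose(out_p, out, atol=1e-10)


# -------------------------------------------------------------- stack_views
def test_three_views_fold_to_two_outputs(rng):
    blocks = [CrossViewBlock(rng, 4, 2) for _ in range(2)]
    ts = [Tensor(rng.standard_normal((5, 4))) for _ in range(3)]
    out = stack_views(ts, blocks)
    assert len(out) == 2


def test_single_view_passes_through(rng):
    t = Tensor(rng.standard_normal((5, 4)))
    out = stack_views([t], [])
    assert out == [t]


def test_zeroed_blocks_propagate_first_view(rng):
    blocks = [zeroed(CrossViewBlock(rng, 4, 2)) for _ in range(3)]
    ts = [Tensor(rng.standard_normal((5, 4))) for _ in range(4)]
    for out in stack_views(ts, blocks):
        np.testing.assert_array_equal(out.data, ts[0].data)


def test_four_view_fold_matches_manual_unroll(rng):
    blocks = [CrossViewBlock(rng, 6, 2) for _ in range(3)]
    ts = [Tensor(rng.standard_normal((4, 6))) for _ in range(4)]
    out = stack_views(ts, blocks)
    s1 = blocks[0](ts[0], ts[1])
    s2 = blocks[1](s1, ts[2])
    s3 = blocks[2](s2, ts[3])
    for got, want in zip(out, (s1, s2, s3)):
        np.testing.assert_allclose(got.data, want.data, atol=1e-12)


def test_empty_view_list_rejected():
    with pytest.raises(ValidationError):
        stack_views([], [])


@pytest.mark.parametrize("v,expected_len", [(1, 1), (2, 2), (3, 2), (5, 2)])
def test_retained_outputs_per_view_count(rng, v, expected_len):
    stack = [Tensor(np.full((2, 3), float(i))) for i in range(max(v - 1, 1))]
    kept = retained_outputs(stack, v)
    assert len(kept) == expected_len
    if v == 2:
        assert kept[0] is kept[1]  # the lone fold output is used twice


# ------------------------------------------------------------- fusion head
def test_default_fusion_widths(rng):
    """d = 96 with two retained matrices per branch: 192 per branch, 384
    fused — the documented head input size."""
    head = FusionHead(rng, 96, 2)
    assert head.in_features == 384
    stacks = [[Tensor(rng.standard_normal((5, 96))) for _ in range(2)]
              for _ in range(2)]
    logits = fuse_and_classify(stacks[0], stacks[1], head, n_views=3)
    assert logits.data.shape == (2,)


def test_zero_head_weights_yield_final_bias(rng):
    head = FusionHead(rng, 4, 2)
    for lin in (head.lin1, head.lin2, head.lin3):
        lin.W.data[:] = 0.0
        lin.b.data[:] = 0.0
    head.lin3.b.data = np.array([0.25, -1.5])
    stacks = [[Tensor(rng.standard_normal((3, 4))) for _ in range(2)]
              for _ in range(2)]
    np.testing.assert_allclose(
        fuse_and_classify(stacks[0], stacks[1], head, 3).data, [0.25, -1.5])


def test_integer_affine_chain(rng):
    """Fixed pooled vectors through small integer weights: hand-evaluated."""
    head = FusionHead(rng, 1, 1, hidden=(2, 2))
    head.lin1.W.data = np.array([[1.0, -1.0], [2.0, 0.0]])
    head.lin1.b.data = np.array([0.0, 1.0])
    head.lin2.W.data = np.array([[1.0, 1.0], [0.0, 2.0]])
    head.lin2.b.data = np.array([0.0, 0.0])
    head.lin3.W.data = np.array([[1.0, 0.0], [1.0, -1.0]])
    head.lin3.b.data = np.array([0.5, 0.5])
    # pooled vectors: pos token matrix [[2]], neg [[3]] -> fconcat [2, 3]
    pos = [Tensor(np.array([[2.0]]))]
    neg = [Tensor(np.array([[3.0]]))]
    # z1 = relu([2*1+3*2, -2]) + b = relu([8, -1]) = [8, 0]
    # z2 = relu([8, 8]) = [8, 8]; z3 = [8+8+0.5, -8+0.5] = [16.5, -7.5]
    np.testing.assert_allclose(fuse_and_classify(pos, neg, head, 1).data,
                               [16.5, -7.5])


def test_wrong_fused_width_reports_both_numbers(rng):
    head = FusionHead(rng, 4, 2)  # expects 16
    stacks = [[Tensor(rng.standard_normal((3, 4)))] for _ in range(2)]
    with pytest.raises(ValidationError, match="8.*16"):
        fuse_and_classify(stacks[0], stacks[1], head, n_views=1)


def test_fusion_invariant_to_token_permutations(rng):
    """Mean pooling + no positional encoding: permuting tokens of any
    retained matrix leaves the logits unchanged."""
    head = FusionHead(rng, 6, 2)
    pos = [rng.standard_normal((5, 6)) for _ in range(2)]
    neg = [rng.standard_normal((5, 6)) for _ in range(2)]
    base = fuse_and_classify([Tensor(p) for p in pos],
                             [Tensor(n) for n in neg], head, 3).data
    perm = rng.permutation(5)
    shuffled = fuse_and_classify([Tensor(p[perm]) for p in pos],
                                 [Tensor(n[perm]) for n in neg], head, 3).data
    np.testing.assert_allclose(shuffled, base, atol=1e-10)
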