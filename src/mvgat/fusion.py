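"""Cross-view fusion: cross-attention transformer blocks folded over the view
sequence, then a flatten–concatenate–linear classification head.

Each branch (positive and negative) carries one encoder-output token
matrix per view. The cross-view block attends from the running fold state
(queries) into the next view's tokens (keys/values) and is applied as a
left fold: ``out[0] = B(T1, T2)``, ``out[k] = B(out[k-1], T_{k+2})``.
With the default three views this produces exactly two intermediates per
branch; those are mean-pooled over tokens (a permutation-invariant
readout that keeps the head width independent of graph size), giving four
pooled d-vectors whose concatenation — 384 at the default d = 96 — feeds
the Linear(384,32) -> Linear(32,16) -> Linear(16,2) head.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Linear, Module
from .transformer import TransformerEncoderBlock
from .views import ValidationError


class CrossViewBlock(Module):
    """Cross-attention transformer block over two views (thin wrapper keeping its
    own parameters; see TransformerEncoderBlock for the data path)."""

    def __init__(self, rng: np.random.Generator, d_model: int,
                 n_heads: int = 4, d_ff: int | None = None, eps: float = 1e-5):
        self.block = TransformerEncoderBlock(rng, d_model, n_heads, d_ff, eps)

    def __call__(self, x1: Tensor, x2: Tensor) -> Tensor:
        return self.block(x1, x2)


def cross_view_step(x1: Tensor, x2: Tensor, block: CrossViewBlock) -> Tensor:
    """LN both views, cross-attend x1 -> x2, residual, MLP, residual.
    Output token count equals x1's."""
    return block(x1, x2)


def stack_views(te_outputs: list[Tensor],
                blocks: list[CrossViewBlock]) -> list[Tensor]:
    """Left fold of cross-view blocks over the per-view encoder outputs.

    Returns the V-1 fold intermediates (for three views: the two matrices
    the head flattens); a single view passes through unchanged.
    """
    if not te_outputs:
        raise ValidationError("stack_views needs at least one view")
    v = len(te_outputs)
    if v == 1:
        return [te_outputs[0]]
    if len(blocks) != v - 1:
        raise ValidationError(
            f"{v} views need {v - 1} cross-view blocks, got {len(blocks)}"
        )
    outs: list[Tensor] = []
    state = te_outputs[0]
    for k in range(1, v):
        state = blocks[k - 1](state, te_outputs[k])
        outs.append(state)
    return outs


def _pool(x: Tensor) -> Tensor:
    """Mean over tokens: (..., S, d) -> (..., d)."""
    return ad.tmean(x, axis=-2)


def retained_outputs(stack: list[Tensor], n_views: int) -> list[Tensor]:
    """Which fold outputs the head flattens: the last two when V >= 3,
    the single block output twice when V = 2 (keeping the head width
    stable), the lone encoder output when V = 1."""
    if n_views == 1:
        return [stack[0]]
    if n_views == 2:
        return [stack[-1], stack[-1]]
    return stack[-2:]


class FusionHead(Module):
    """Pooled-feature classifier: concat -> Linear -> ReLU -> Linear ->
    ReLU -> Linear, emitting 2-class logits."""

    def __init__(self, rng: np.random.Generator, d_model: int, n_flat: int,
                 hidden: tuple[int, int] = (32, 16), n_classes: int = 2):
        self.in_features = 2 * n_flat * d_model
        self.lin1 = Linear(rng, self.in_features, hidden[0])
        self.lin2 = Linear(rng, hidden[0], hidden[1])
        self.lin3 = Linear(rng, hidden[1], n_classes)

    def __call__(self, fconcat: Tensor) -> Tensor:
        if fconcat.shape[-1] != self.in_features:
            raise ValidationError(
                f"fused feature length {fconcat.shape[-1]} does not match "
                f"head in_features {self.in_features}"
            )
        z1 = ad.relu(self.lin1(fconcat))
        z2 = ad.relu(self.lin2(z1))
        return self.lin3(z2)


def fuse_and_classify(pos_stack: list[Tensor], neg_stack: list[Tensor],
                      head: FusionHead, n_views: int) -> Tensor:
    """Pool the retained cross-view outputs of both branches, concatenate
    positives then negatives, and classify."""
    fx = ad.concat([_pool(t) for t in retained_outputs(pos_stack, n_views)],
                   axis=-1)
    fy = ad.concat([_pool(t) for t in retained_outputs(neg_stack, n_views)],
                   axis=-1)
    return head(ad.concat([fx, fy], axis=-1))
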