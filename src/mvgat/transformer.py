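"""Transformer primitives: scaled dot-product attention, multi-head
attention, the position-wise feed-forward network, layer normalization,
and the pre-norm residual encoder block.

Node tokens are unordered brain regions, so there is no positional
encoding anywhere; every block is permutation-equivariant over tokens.
The encoder block doubles as the cross-view block: self-attention is the
special case where queries and keys/values come from the same token
matrix.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Linear, Module
from .views import ValidationError


def scaled_dot_attention(Q, K, V):
    """softmax(Q K^T / sqrt(d_k)) V, rows of the implicit weight matrix
    summing to 1; accepts Tensors or arrays, with leading batch axes."""
    q = Q if isinstance(Q, Tensor) else Tensor(Q)
    k = K if isinstance(K, Tensor) else Tensor(K)
    v = V if isinstance(V, Tensor) else Tensor(V)
    if q.shape[-1] != k.shape[-1]:
        raise ValidationError(
            f"query width {q.shape[-1]} != key width {k.shape[-1]}"
        )
    if k.shape[-2] != v.shape[-2]:
        raise ValidationError("K and V must have the same number of rows")
    d_k = q.shape[-1]
    scores = ad.mul(ad.matmul(q, ad.swapaxes(k, -1, -2)), 1.0 / np.sqrt(d_k))
    weights = ad.softmax(scores, axis=-1)
    out = ad.matmul(weights, v)
    if not isinstance(Q, Tensor):
        return out.data
    return out


class MultiHeadAttention(Module):
    """h parallel attention heads with output projection (no biases).

    ``__call__(query_src, kv_src)``: queries from the first argument, keys
    and values from the second; pass the same matrix twice for
    self-attention.
    """

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int):
        if d_model % n_heads != 0:
            raise ValidationError(
                f"n_heads={n_heads} must divide d_model={d_model}"
            )
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.W_q = Linear(rng, d_model, d_model, bias=False)
        self.W_k = Linear(rng, d_model, d_model, bias=False)
        self.W_v = Linear(rng, d_model, d_model, bias=False)
        self.W_o = Linear(rng, d_model, d_model, bias=False)

    def _split(self, x: Tensor) -> Tensor:
        # (..., S, d) -> (..., h, S, d_k)
        shape = x.shape[:-1] + (self.n_heads, self.d_k)
        return ad.swapaxes(ad.reshape(x, shape), -2, -3)

    def __call__(self, query_src: Tensor, kv_src: Tensor) -> Tensor:
        if query_src.shape[-1] != self.d_model or kv_src.shape[-1] != self.d_model:
            raise ValidationError(
                f"inputs must have width {self.d_model}, got "
                f"{query_src.shape[-1]} and {kv_src.shape[-1]}"
            )
        q = self._split(self.W_q(query_src))
        k = self._split(self.W_k(kv_src))
        v = self._split(self.W_v(kv_src))
        heads = scaled_dot_attention(q, k, v)  # (..., h, S_q, d_k)
        merged = ad.swapaxes(heads, -2, -3)
        merged = ad.reshape(merged, merged.shape[:-2] + (self.d_model,))
        return self.W_o(merged)


class FeedForward(Module):
    """Two-layer position-wise network ReLU(x W1 + b1) W2 + b2; also the
    MLP of the cross-view block (same algebraic form)."""

    def __init__(self, rng: np.random.Generator, d_model: int, d_ff: int):
        self.lin1 = Linear(rng, d_model, d_ff)
        self.lin2 = Linear(rng, d_ff, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(ad.relu(self.lin1(x)))


class LayerNorm(Module):
    """Per-token normalization (x - mu) / sqrt(var + eps) * gamma + beta,
    with mu/var the row mean and population variance."""

    def __init__(self, d_model: int, eps: float = 1e-5):
        self.eps = float(eps)
        self.gamma = Tensor(np.ones(d_model), requires_grad=True)
        self.beta = Tensor(np.zeros(d_model), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = ad.tmean(x, axis=-1, keepdims=True)
        centered = ad.add(x, ad.mul(mu, -1.0))
        var = ad.tmean(ad.mul(centered, centered), axis=-1, keepdims=True)
        inv = ad.power(ad.add(var, self.eps), -0.5)
        return ad.add(ad.mul(ad.mul(centered, inv), self.gamma), self.beta)


class TransformerEncoderBlock(Module):
    """Pre-norm residual block.

    ``__call__(x)`` is the encoder: R1 = x + MHA(LN(x), LN(x)) and
    output = R1 + FFN(LN(R1)). ``__call__(x1, x2)`` is the cross-view
    form: both inputs pass through the same first LayerNorm, queries come
    from x1 and keys/values from x2, and both residual additions run off
    x1, so the output keeps x1's token count.
    """

    def __init__(self, rng: np.random.Generator, d_model: int,
                 n_heads: int = 4, d_ff: int | None = None, eps: float = 1e-5):
        d_ff = 2 * d_model if d_ff is None else d_ff
        self.ln_attn = LayerNorm(d_model, eps)
        self.ln_mlp = LayerNorm(d_model, eps)
        self.mha = MultiHeadAttention(rng, d_model, n_heads)
        self.mlp = FeedForward(rng, d_model, d_ff)

    def __call__(self, x1: Tensor, x2: Tensor | None = None) -> Tensor:
        if x2 is None:
            x2 = x1
        if x1.shape[-1] != x2.shape[-1]:
            raise ValidationError(
                f"token widths differ: {x1.shape[-1]} vs {x2.shape[-1]}"
            )
        n1 = self.ln_attn(x1)
        n2 = n1 if x2 is x1 else self.ln_attn(x2)
        r1 = ad.add(x1, self.mha(n1, n2))
        return ad.add(r1, self.mlp(self.ln_mlp(r1)))
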