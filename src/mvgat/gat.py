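"""Graph attention layer.

Each node i carries a feature vector; a shared linear map ``W`` projects
it, a single-layer scorer ``LeakyReLU(a^T [Wh_i || Wh_j])`` produces
attention logits over the first-order neighborhood ``N_i`` (which always
contains i itself, so the softmax is defined even for isolated nodes), and
the output is the attention-weighted sum of projected neighbor features.
Edge weights of the view adjacency are used for masking only; the scores
are feature-driven.

The layer runs on batched inputs ``(..., N, F)`` with a boolean mask
``(..., N, N)``; the standalone :func:`gat_attention` / :func:`gat_forward`
helpers expose the single-graph numpy contract used in tests and docs.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, glorot
from .views import ValidationError

_MASK_FILL = -1e30


class GATLayer(Module):
    """One graph-attention head. ``activation``: 'elu' or 'none'."""

    def __init__(self, rng: np.random.Generator, in_features: int,
                 out_features: int, leaky_slope: float = 0.2,
                 activation: str = "elu"):
        if out_features < 1:
            raise ValidationError("out_features must be >= 1")
        if activation not in ("elu", "none"):
            raise ValidationError(f"unknown activation {activation!r}")
        self.in_features = in_features
        self.out_features = out_features
        self.leaky_slope = float(leaky_slope)
        self.activation = activation
        # W maps F -> F'; attention vector a scores [Wh_i || Wh_j]
        self.W = glorot(rng, in_features, out_features)
        self.a_src = glorot(rng, 2 * out_features, 1, shape=(out_features, 1))
        self.a_dst = glorot(rng, 2 * out_features, 1, shape=(out_features, 1))

    # ------------------------------------------------------------------ core
    def attention(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """Masked attention coefficients alpha, rows summing to 1 on N_i."""
        if x.shape[-1] != self.in_features:
            raise ValidationError(
                f"feature width {x.shape[-1]} != layer in_features "
                f"{self.in_features}"
            )
        h = ad.matmul(x, self.W)  # (..., N, F')
        s = ad.matmul(h, self.a_src)  # (..., N, 1)
        t = ad.matmul(h, self.a_dst)  # (..., N, 1)
        e = ad.leaky_relu(ad.add(s, ad.swapaxes(t, -1, -2)), self.leaky_slope)
        e = ad.where_mask(mask, e, _MASK_FILL)
        alpha = ad.softmax(e, axis=-1)
        return ad.where_mask(mask, alpha, 0.0)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        if np.isnan(x.data).any():
            raise ValidationError("NaN in node features")
        h = ad.matmul(x, self.W)
        alpha = self.attention(x, mask)
        out = ad.matmul(alpha, h)
        if self.activation == "elu":
            out = ad.elu(out)
        return out


# ------------------------------------------------- single-graph numpy facade
def _mask_from_neighborhoods(n: int, neighborhoods) -> np.ndarray:
    mask = np.zeros((n, n), dtype=bool)
    for i, nbrs in enumerate(neighborhoods):
        if len(nbrs) == 0:
            raise ValidationError(f"empty neighborhood for node {i}")
        mask[i, np.asarray(nbrs, dtype=int)] = True
        mask[i, i] = True
    return mask


def gat_attention(features: np.ndarray, layer: GATLayer,
                  neighborhoods) -> np.ndarray:
    """Attention matrix for one graph: alpha[i, j] = 0 off-neighborhood,
    each row summing to 1 over N_i."""
    features = np.asarray(features, dtype=np.float64)
    mask = _mask_from_neighborhoods(features.shape[0], neighborhoods)
    return layer.attention(Tensor(features), mask).data


def gat_forward(features: np.ndarray, layer: GATLayer,
                neighborhoods) -> np.ndarray:
    """Forward pass for one graph: attention-weighted sums of W h_j."""
    features = np.asarray(features, dtype=np.float64)
    mask = _mask_from_neighborhoods(features.shape[0], neighborhoods)
    return layer(Tensor(features), mask).data
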