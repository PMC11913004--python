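"""End-to-end multi-view signed-graph classifier.

Per view and per sign channel: GAT-1 (ELU) -> residual addition with a
projected skip of the raw node features -> GAT-2 (linear). The two sign
channels are mean-pooled, concatenated (128 wide at the defaults) and fed
through a per-view Linear(128,16) -> Linear(16,2) auxiliary head. Each
sign channel's GAT-2 tokens are lifted 64 -> 96 and passed through a
transformer encoder; the per-view encoder outputs are folded by
cross-view blocks separately for the positive and negative branches, and
the fusion head (Linear(384,32) -> (32,16) -> (16,2) at the defaults)
produces the diagnostic logits. Prediction uses the fusion head only; the
per-view heads contribute an auxiliary loss term.

All parameters are Glorot-initialised from a single seeded generator, so
a config + seed pins every weight; the checkpoint stores the raw float64
arrays keyed by module path plus the config, and a load/evaluate
round-trip is bitwise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fusion import CrossViewBlock, FusionHead, fuse_and_classify, stack_views
from .gat import GATLayer
from .nn import Linear, Module
from .transformer import TransformerEncoderBlock
from .views import ValidationError, ViewGraph


@dataclass
class ModelConfig:
    V: int = 3
    n_regions: int = 32
    feature_dim: int | None = None  # defaults to n_regions (fc-row features)
    gat_hidden: int = 64
    gat_out: int = 64
    te_dim: int = 96
    te_heads: int = 4
    te_layers: int = 1
    view_head_hidden: int = 16
    fusion_hidden: tuple[int, int] = (32, 16)
    aux_loss_weight: float = 0.5
    dropout: float = 0.0
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.feature_dim is None:
            self.feature_dim = self.n_regions
        if self.aux_loss_weight < 0:
            raise ValidationError("aux_loss_weight must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")
        self.fusion_hidden = tuple(self.fusion_hidden)

    @property
    def n_flat(self) -> int:
        """Pooled matrices per branch entering the fusion head."""
        return 1 if self.V == 1 else 2

    @property
    def view_concat_width(self) -> int:
        return 2 * self.gat_out

    @property
    def fusion_in_features(self) -> int:
        return 2 * self.n_flat * self.te_dim


@dataclass
class ModelOutput:
    fusion_logits: np.ndarray  # (2,)
    per_view_logits: list[np.ndarray]  # V entries of shape (2,)
    predicted_label: int


class _SignBranch(Module):
    """GAT-1 / residual / GAT-2 for one (view, sign) channel."""

    def __init__(self, rng, cfg: ModelConfig):
        self.gat1 = GATLayer(rng, cfg.feature_dim, cfg.gat_hidden,
                             cfg.leaky_slope, activation="elu")
        self.skip = (Linear(rng, cfg.feature_dim, cfg.gat_hidden)
                     if cfg.feature_dim != cfg.gat_hidden else None)
        self.gat2 = GATLayer(rng, cfg.gat_hidden, cfg.gat_out,
                             cfg.leaky_slope, activation="none")
        self.te_proj = Linear(rng, cfg.gat_out, cfg.te_dim)
        self.te_blocks = [TransformerEncoderBlock(rng, cfg.te_dim, cfg.te_heads)
                          for _ in range(cfg.te_layers)]

    def __call__(self, feats: Tensor, mask: np.ndarray):
        g1 = self.gat1(feats, mask)
        skip = self.skip(feats) if self.skip is not None else feats
        r = ad.add(g1, skip)
        g2 = self.gat2(r, mask)  # (..., N, gat_out)
        tokens = self.te_proj(g2)
        for blk in self.te_blocks:
            tokens = blk(tokens)
        return g2, tokens


class _ViewHead(Module):
    def __init__(self, rng, cfg: ModelConfig):
        self.lin1 = Linear(rng, cfg.view_concat_width, cfg.view_head_hidden)
        self.lin2 = Linear(rng, cfg.view_head_hidden, 2)

    def __call__(self, pooled: Tensor) -> Tensor:
        return self.lin2(ad.relu(self.lin1(pooled)))


class MVGATModel(Module):
    """The full multi-view model; see the module docstring for the data
    path. A ``coarsen`` hook (callable ``(features, mask) -> (features,
    mask)``) is an extension point for graph coarsening; default off."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.coarsen = None
        self.pos_branches = [_SignBranch(rng, cfg) for _ in range(cfg.V)]
        self.neg_branches = [_SignBranch(rng, cfg) for _ in range(cfg.V)]
        self.view_heads = [_ViewHead(rng, cfg) for _ in range(cfg.V)]
        n_blocks = max(cfg.V - 1, 0)
        self.pos_fold = [CrossViewBlock(rng, cfg.te_dim, cfg.te_heads)
                         for _ in range(n_blocks)]
        self.neg_fold = [CrossViewBlock(rng, cfg.te_dim, cfg.te_heads)
                         for _ in range(n_blocks)]
        self.fusion_head = FusionHead(rng, cfg.te_dim, cfg.n_flat,
                                      hidden=cfg.fusion_hidden)

    # -------------------------------------------------------------- forward
    def forward_batch(self, pos, neg, train_rng: np.random.Generator | None = None):
        """Batched forward pass.

        ``pos`` / ``neg``: lists of V ``(features, mask)`` pairs ordered by
        view index, features ``(B, N, F)`` arrays, masks ``(B, N, N)``
        boolean. Returns ``(fusion_logits (B, 2), per_view_logits list)``.
        ``train_rng`` enables dropout (rate ``cfg.dropout``) on the encoder
        inputs and fused features.
        """
        cfg = self.cfg
        if len(pos) != cfg.V or len(neg) != cfg.V:
            raise ValidationError(
                f"expected {cfg.V} views per sign, got {len(pos)}+/{len(neg)}-"
            )
        drop = cfg.dropout if train_rng is not None else 0.0

        def maybe_drop(t: Tensor) -> Tensor:
            if drop <= 0.0:
                return t
            keep = (train_rng.random(t.shape) >= drop) / (1.0 - drop)
            return ad.mul(t, Tensor(keep))

        per_view_logits = []
        pos_tokens, neg_tokens = [], []
        for v in range(cfg.V):
            pf, pm = pos[v]
            nf, nm = neg[v]
            if self.coarsen is not None:
                pf, pm = self.coarsen(pf, pm)
                nf, nm = self.coarsen(nf, nm)
            pf = pf if isinstance(pf, Tensor) else Tensor(pf)
            nf = nf if isinstance(nf, Tensor) else Tensor(nf)
            if pf.shape != nf.shape:
                raise ValidationError(
                    f"view {v + 1}: +/- graphs disagree in size "
                    f"({pf.shape} vs {nf.shape})"
                )
            g2p, tp = self.pos_branches[v](pf, pm)
            g2n, tn = self.neg_branches[v](nf, nm)
            pooled = ad.concat(
                [ad.tmean(g2p, axis=-2), ad.tmean(g2n, axis=-2)], axis=-1
            )
            per_view_logits.append(self.view_heads[v](pooled))
            pos_tokens.append(maybe_drop(tp))
            neg_tokens.append(maybe_drop(tn))
        pos_stack = stack_views(pos_tokens, self.pos_fold)
        neg_stack = stack_views(neg_tokens, self.neg_fold)
        fusion_logits = fuse_and_classify(pos_stack, neg_stack,
                                          self.fusion_head, cfg.V)
        return fusion_logits, per_view_logits


def _group_views(sample_views: list[ViewGraph], V: int):
    by_key = {(g.sign, g.view_index): g for g in sample_views}
    pos, neg = [], []
    for v in range(1, V + 1):
        for sign, dest in (("+", pos), ("-", neg)):
            g = by_key.get((sign, v))
            if g is None:
                raise ValidationError(f"missing view graph (view {v}, sign '{sign}')")
            dest.append((g.node_features[None], g.attention_mask()[None]))
    return pos, neg


def model_forward(sample_views: list[ViewGraph], model: MVGATModel) -> ModelOutput:
    """Single-subject forward pass over its 2V view graphs."""
    if len(sample_views) != 2 * model.cfg.V:
        raise ValidationError(
            f"expected {2 * model.cfg.V} view graphs, got {len(sample_views)}"
        )
    pos, neg = _group_views(sample_views, model.cfg.V)
    fusion, per_view = model.forward_batch(pos, neg)
    fl = fusion.data[0]
    return ModelOutput(
        fusion_logits=fl,
        per_view_logits=[p.data[0] for p in per_view],
        predicted_label=int(np.argmax(fl)),
    )


# ------------------------------------------------------------------- loss
def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``logits`` (B, C), ``labels`` (B,) ints."""
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    lse = ad.logsumexp(logits, axis=-1)  # (B,)
    picked = ad.getitem(logits, (np.arange(len(labels)), labels))
    return ad.tmean(ad.add(lse, ad.mul(picked, -1.0)))


def total_loss(fusion_logits: Tensor, per_view_logits: list[Tensor],
               labels: np.ndarray, aux_weight: float) -> Tensor:
    """Fusion cross-entropy plus ``aux_weight`` times the summed per-view
    head cross-entropies."""
    if aux_weight < 0:
        raise ValidationError("aux_weight must be >= 0")
    loss = cross_entropy(fusion_logits, labels)
    if aux_weight > 0:
        for pv in per_view_logits:
            loss = ad.add(loss, ad.mul(cross_entropy(pv, labels), aux_weight))
    return loss


# -------------------------------------------------------------- checkpoint
def save_checkpoint(path: str | Path, model: MVGATModel) -> None:
    """One archive: every parameter array keyed by module path, plus the
    config as JSON."""
    params = model.named_parameters()
    arrays = {k: p.data for k, p in params.items()}
    cfg = asdict(model.cfg)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> MVGATModel:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["fusion_hidden"] = tuple(cfg_dict["fusion_hidden"])
        cfg = ModelConfig(**cfg_dict)
        model = MVGATModel(cfg)
        params = model.named_parameters()
        for key, p in params.items():
            if key not in data:
                raise ValidationError(f"checkpoint missing parameter {key}")
            arr = data[key]
            if arr.shape != p.data.shape:
                raise ValidationError(
                    f"checkpoint shape mismatch for {key}: "
                    f"{arr.shape} vs {p.data.shape}"
                )
            p.data = arr.astype(np.float64)
    return model
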