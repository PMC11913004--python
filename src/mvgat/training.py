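"""Training, evaluation and stratified cross-validation.

Subjects' view graphs are precomputed once per run and stacked into
batched arrays (features ``(n, N, F)``, masks ``(n, N, N)`` per view and
sign), so each optimization step is a handful of large numpy ops instead
of per-subject Python loops. The optimizer is Adam with L2 weight decay;
the objective is the fusion cross-entropy plus the auxiliary per-view
head terms. Everything is seeded: fold assignment, weight init, and
minibatch shuffling derive from the run seed, so repeated runs reproduce
metrics bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .model import MVGATModel, ModelConfig, total_loss
from .views import (ConnectivitySample, ValidationError, ViewConfig,
                    build_views, load_cohort)


# ---------------------------------------------------------------- metrics
@dataclass
class MetricsReport:
    """Confusion counts plus the derived rates for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float  # nan when undefined (single-class evaluation set)
    n: int

    def __post_init__(self):
        assert self.tp + self.fp + self.tn + self.fn == self.n
        assert abs(self.accuracy - (self.tp + self.tn) / self.n) < 1e-12
        if self.tp + self.fn > 0:
            assert abs(self.sensitivity - self.tp / (self.tp + self.fn)) < 1e-12
        if self.tn + self.fp > 0:
            assert abs(self.specificity - self.tn / (self.tn + self.fp)) < 1e-12

    @classmethod
    def from_scores(cls, scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> "MetricsReport":
        """Build from positive-class probabilities and true labels.

        AUC is the Mann-Whitney rank statistic (ties count 1/2); it is
        nan when only one class is present.
        """
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        pred = (scores >= threshold).astype(int)
        tp = int(np.sum((pred == 1) & (labels == 1)))
        fp = int(np.sum((pred == 1) & (labels == 0)))
        tn = int(np.sum((pred == 0) & (labels == 0)))
        fn = int(np.sum((pred == 0) & (labels == 1)))
        n = len(labels)
        auc = (float(roc_auc_score(labels, scores))
               if len(np.unique(labels)) == 2 else float("nan"))
        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            accuracy=(tp + tn) / n,
            sensitivity=tp / (tp + fn) if tp + fn > 0 else float("nan"),
            specificity=tn / (tn + fp) if tn + fp > 0 else float("nan"),
            auc=auc, n=n,
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "tn", "fn", "accuracy", "sensitivity",
                 "specificity", "auc", "n")}


@dataclass
class OptimizerConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    epochs: int = 100
    batch_size: int = 16


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    views: ViewConfig = field(default_factory=ViewConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    cv_folds: int = 5
    val_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


# ----------------------------------------------------------- data plumbing
class CohortTensors:
    """Whole-cohort batched view arrays; index with a subject id array."""

    def __init__(self, samples: list[ConnectivitySample], views: ViewConfig):
        self.subject_ids = [s.subject_id for s in samples]
        self.labels = np.array([s.label for s in samples], dtype=int)
        v = views.V
        pos_f = [[] for _ in range(v)]
        pos_m = [[] for _ in range(v)]
        neg_f = [[] for _ in range(v)]
        neg_m = [[] for _ in range(v)]
        for s in samples:
            graphs = build_views(s, views)
            for g in graphs:
                (pos_f if g.sign == "+" else neg_f)[g.view_index - 1].append(
                    g.node_features)
                (pos_m if g.sign == "+" else neg_m)[g.view_index - 1].append(
                    g.attention_mask())
        self.pos = [(np.stack(pos_f[i]), np.stack(pos_m[i])) for i in range(v)]
        self.neg = [(np.stack(neg_f[i]), np.stack(neg_m[i])) for i in range(v)]

    def __len__(self):
        return len(self.labels)

    def subset(self, idx: np.ndarray):
        pos = [(f[idx], m[idx]) for f, m in self.pos]
        neg = [(f[idx], m[idx]) for f, m in self.neg]
        return pos, neg, self.labels[idx]


# ---------------------------------------------------------------- optimizer
class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ------------------------------------------------------------------- train
def _scores(model: MVGATModel, tensors: CohortTensors,
            idx: np.ndarray | None = None, chunk: int = 64) -> np.ndarray:
    """Positive-class fusion probabilities, computed in chunks."""
    idx = np.arange(len(tensors)) if idx is None else idx
    out = np.empty(len(idx))
    for start in range(0, len(idx), chunk):
        sel = idx[start:start + chunk]
        pos, neg, _ = tensors.subset(sel)
        logits, _ = model.forward_batch(pos, neg)
        z = logits.data
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        out[start:start + len(sel)] = (e[:, 1] / e.sum(axis=1))
    return out


def train(samples_or_tensors, cfg: RunConfig,
          model: MVGATModel | None = None):
    """Fit a model on a cohort; returns ``(model, history)``.

    History holds one record per epoch with the mean train loss and, if
    ``val_fraction > 0``, held-out accuracy/AUC. A non-finite loss aborts
    with the offending batch's subject ids.
    """
    tensors = (samples_or_tensors
               if hasattr(samples_or_tensors, "subset")
               else CohortTensors(samples_or_tensors, cfg.views))
    if model is None:
        model = MVGATModel(cfg.model)
    params = model.named_parameters()
    opt = Adam(params, cfg.optimizer.learning_rate,
               cfg.optimizer.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    all_idx = np.arange(len(tensors))
    val_idx = np.array([], dtype=int)
    train_idx = all_idx
    if cfg.val_fraction > 0:
        train_idx, val_idx = train_test_split(
            all_idx, test_size=cfg.val_fraction, random_state=cfg.seed,
            stratify=tensors.labels)
    history = []
    bs = cfg.optimizer.batch_size
    drop_rng = (np.random.default_rng(rng.integers(2**31))
                if cfg.model.dropout > 0 else None)
    for epoch in range(cfg.optimizer.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), bs):
            sel = order[start:start + bs]
            pos, neg, labels = tensors.subset(sel)
            model.zero_grad()
            try:
                fusion, per_view = model.forward_batch(pos, neg,
                                                       train_rng=drop_rng)
                loss = total_loss(fusion, per_view, labels,
                                  cfg.model.aux_loss_weight)
                finite = np.isfinite(loss.data)
            except ValidationError as err:  # diverged weights propagate NaN
                if "NaN" not in str(err):
                    raise
                finite = False
            if not finite:
                ids = [tensors.subject_ids[i] for i in sel]
                raise RuntimeError(f"non-finite loss on batch {ids}")
            if cfg.optimizer.learning_rate > 0:
                loss.backward()
                opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if len(val_idx):
            s = _scores(model, tensors, val_idx)
            rep = MetricsReport.from_scores(s, tensors.labels[val_idx])
            record["val_accuracy"] = rep.accuracy
            record["val_auc"] = rep.auc
        history.append(record)
    return model, history


def evaluate(model: MVGATModel, samples_or_tensors,
             views: ViewConfig | None = None) -> MetricsReport:
    """Score every subject and report confusion counts, accuracy,
    sensitivity, specificity and AUC (fusion softmax thresholded at 0.5)."""
    tensors = (samples_or_tensors
               if hasattr(samples_or_tensors, "subset")
               else CohortTensors(samples_or_tensors,
                                  views if views is not None else ViewConfig(
                                      V=model.cfg.V)))
    scores = _scores(model, tensors)
    return MetricsReport.from_scores(scores, tensors.labels)


def cross_validate(samples: list[ConnectivitySample], cfg: RunConfig):
    """Stratified k-fold with per-fold training from scratch.

    Returns ``(reports, summary)``: one MetricsReport per fold and a
    summary with mean and sd of each metric over folds.
    """
    labels = np.array([s.label for s in samples])
    counts = np.bincount(labels, minlength=2)
    if cfg.cv_folds > counts.min():
        raise ValidationError(
            f"cannot stratify {cfg.cv_folds} folds with class counts "
            f"{counts.tolist()}"
        )
    tensors = CohortTensors(samples, cfg.views)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                          random_state=cfg.seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_cfg = RunConfig(
            model=ModelConfig(**{**vars(cfg.model),
                                 "seed": cfg.model.seed + fold}),
            views=cfg.views, optimizer=cfg.optimizer,
            cv_folds=cfg.cv_folds, seed=cfg.seed + fold)
        sub = _SubsetTensors(tensors, tr)
        model, _ = train(sub, fold_cfg)
        scores = _scores(model, tensors, te)
        reports.append(MetricsReport.from_scores(scores, labels[te]))
    summary = {}
    for key in ("accuracy", "sensitivity", "specificity", "auc"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        summary[f"{key}_mean"] = float(np.nanmean(vals))
        summary[f"{key}_sd"] = float(np.nanstd(vals))
    return reports, summary


class _SubsetTensors:
    """View of a CohortTensors restricted to a subject index set."""

    def __init__(self, base: CohortTensors, idx: np.ndarray):
        self._base = base
        self._idx = np.asarray(idx)
        self.labels = base.labels[self._idx]
        self.subject_ids = [base.subject_ids[i] for i in self._idx]

    def __len__(self):
        return len(self._idx)

    def subset(self, idx: np.ndarray):
        return self._base.subset(self._idx[idx])


# --------------------------------------------------------------- manifests
def evaluate_manifest(model: MVGATModel, manifest_path: str | Path,
                      views: ViewConfig | None = None) -> MetricsReport:
    return evaluate(model, load_cohort(manifest_path), views)


def write_history(path: str | Path, history: list[dict]) -> None:
    with open(path, "w") as fh:
        for rec in history:
            fh.write(json.dumps(rec) + "\n")
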