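"""Signed multi-view construction from functional-connectivity matrices.

A subject's functional connectome is a symmetric region-by-region Pearson
correlation matrix with unit diagonal. The model consumes it as ``2 * V``
graphs: the positive and negative halves of the matrix (hypo- and
hyper-connectivity carry distinct signal in ASD cohorts), each sparsified
at ``V`` graded edge-retention fractions so that successive views expose
the connectome at increasing density. Edge sets of denser views nest the
sparser ones by construction.

File dialects: matrices are delimited text (comma or tab, autodetected, no
header); cohort manifests are TSV with columns ``subject_id``, ``path``,
``label`` and a header row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-8


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# --------------------------------------------------------------------- types
@dataclass
class ConnectivitySample:
    """One subject: symmetric N-by-N correlation matrix plus binary label."""

    subject_id: str
    fc: np.ndarray
    label: int

    def __post_init__(self):
        self.fc = np.asarray(self.fc, dtype=np.float64)
        validate_fc(self.fc)
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def n_regions(self) -> int:
        return self.fc.shape[0]


@dataclass
class ViewGraph:
    """One (view, sign) graph: masked adjacency plus node features."""

    view_index: int  # 1-based
    sign: str  # '+' or '-'
    adjacency: np.ndarray  # nonnegative, zero diagonal
    node_features: np.ndarray  # (N, F)
    neighborhoods: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValidationError("adjacency must be square")
        if np.any(self.adjacency < 0):
            raise ValidationError("adjacency must be nonnegative")
        if self.node_features.shape[0] != n:
            raise ValidationError(
                f"node_features has {self.node_features.shape[0]} rows "
                f"but adjacency is {n}x{n}"
            )
        if not self.neighborhoods:
            self.neighborhoods = neighborhoods_of(self.adjacency)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def attention_mask(self) -> np.ndarray:
        """Boolean N-by-N mask: nonzero adjacency plus self-loops."""
        mask = self.adjacency > 0
        np.fill_diagonal(mask, True)
        return mask


@dataclass
class ViewConfig:
    """How many views and how dense each one is.

    ``densities`` are edge-retention fractions in (0, 1], strictly
    increasing so distinct views carry distinct sparsity. When omitted
    they are spaced evenly over [0.2, 0.8].
    """

    V: int = 3
    densities: tuple[float, ...] | None = None
    feature_mode: str = "fc_row"

    def __post_init__(self):
        if self.V < 1:
            raise ValidationError(f"V must be >= 1, got {self.V}")
        if self.densities is None:
            if self.V == 1:
                self.densities = (0.5,)
            else:
                self.densities = tuple(np.linspace(0.2, 0.8, self.V))
        self.densities = tuple(float(d) for d in self.densities)
        if len(self.densities) != self.V:
            raise ValidationError(
                f"need {self.V} densities, got {len(self.densities)}"
            )
        if any(not (0.0 < d <= 1.0) for d in self.densities):
            raise ValidationError("densities must lie in (0, 1]")
        if any(b <= a for a, b in zip(self.densities, self.densities[1:])):
            raise ValidationError("densities must be strictly increasing")
        if self.feature_mode not in ("fc_row", "degree", "identity"):
            raise ValidationError(f"unknown feature_mode {self.feature_mode!r}")


# ---------------------------------------------------------------- validation
def validate_fc(fc: np.ndarray) -> None:
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValidationError(f"fc must be square, got shape {fc.shape}")
    if fc.shape[0] < 3:
        raise ValidationError(f"need at least 3 regions, got {fc.shape[0]}")
    asym = np.abs(fc - fc.T)
    if asym.max() > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"fc not symmetric: |fc[{i},{j}] - fc[{j},{i}]| = {asym[i, j]:.3g}"
        )
    if not np.allclose(np.diag(fc), 1.0, atol=1e-8):
        raise ValidationError("fc diagonal must be 1")


def neighborhoods_of(adjacency: np.ndarray) -> list[np.ndarray]:
    """Per-node neighbor index sets: nonzero adjacency entries plus self."""
    n = adjacency.shape[0]
    out = []
    for i in range(n):
        nz = np.flatnonzero(adjacency[i] > 0)
        out.append(np.unique(np.append(nz, i)))
    return out


# ---------------------------------------------------------------- operations
def signed_split(fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a symmetric correlation matrix into nonnegative halves.

    ``pos`` keeps positive off-diagonal correlations, ``neg`` the magnitudes
    of negative ones; both diagonals are zero, and ``pos - neg + I``
    reconstructs the input exactly.
    """
    fc = np.asarray(fc, dtype=np.float64)
    validate_fc(fc)
    off = fc - np.diag(np.diag(fc))
    pos = np.maximum(off, 0.0)
    neg = np.maximum(-off, 0.0)
    return pos, neg


def _retain_topk(half: np.ndarray, density: float) -> np.ndarray:
    """Keep the ceil(density * P) largest upper-triangle entries, mirrored.

    P counts the strictly positive candidates of this sign half. Ties are
    broken by (weight desc, smaller node index, larger node index) so the
    result is deterministic across platforms.
    """
    n = half.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = half[iu, ju]
    cand = w > 0
    p = int(cand.sum())
    if p == 0:
        return np.zeros_like(half)
    k = math.ceil(density * p)
    order = sorted(
        (idx for idx in range(len(w)) if cand[idx]),
        key=lambda idx: (-w[idx], iu[idx], ju[idx]),
    )
    keep = order[:k]
    out = np.zeros_like(half)
    out[iu[keep], ju[keep]] = w[keep]
    out[ju[keep], iu[keep]] = w[keep]
    return out


def _node_features(signed_half: np.ndarray, adjacency: np.ndarray,
                   mode: str) -> np.ndarray:
    n = signed_half.shape[0]
    if mode == "fc_row":
        return signed_half.copy()
    if mode == "degree":
        return (adjacency > 0).sum(axis=1, keepdims=True).astype(np.float64)
    return np.eye(n)


def build_views(sample: ConnectivitySample, cfg: ViewConfig) -> list[ViewGraph]:
    """Build the ``2 * V`` signed view graphs for one subject.

    Returns positives for views 1..V followed by negatives for views 1..V.
    A sign channel with no surviving edges degrades to self-loops only
    (with a warning) so the graph stays processable.
    """
    pos, neg = signed_split(sample.fc)
    graphs: list[ViewGraph] = []
    for sign, half in (("+", pos), ("-", neg)):
        for v, rho in enumerate(cfg.densities, start=1):
            adj = _retain_topk(half, rho)
            if adj.max() == 0:
                warnings.warn(
                    f"subject {sample.subject_id}: view {v} sign '{sign}' has no "
                    "edges; keeping self-loops only",
                    stacklevel=2,
                )
            feats = _node_features(half, adj, cfg.feature_mode)
            graphs.append(ViewGraph(view_index=v, sign=sign,
                                    adjacency=adj, node_features=feats))
    # interleave to pos list then neg list is already the order built
    return graphs


# ------------------------------------------------------------------------ IO
def load_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited-text square matrix; comma or tab autodetected."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        delim = "\t"
    elif "," in first:
        delim = ","
    else:
        delim = None  # whitespace
    mat = np.loadtxt(path, delimiter=delim, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"{path}: expected a square matrix, got {mat.shape}")
    return mat


def save_matrix(path: str | Path, mat: np.ndarray) -> None:
    np.savetxt(path, np.asarray(mat), delimiter=",", fmt="%.10g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest (TSV: subject_id, path, label)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = {"subject_id", "path", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValidationError("manifest labels must be 0/1")
    return df


def load_cohort(manifest_path: str | Path) -> list[ConnectivitySample]:
    """Load every subject listed in a manifest; paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    samples = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        samples.append(
            ConnectivitySample(subject_id=str(row.subject_id),
                               fc=load_matrix(p), label=int(row.label))
        )
    return samples
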