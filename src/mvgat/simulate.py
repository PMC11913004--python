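"""Synthetic two-class connectome cohorts.

Emulates resting-state functional connectivity the way it is computed in
practice: each subject is a multivariate Gaussian time series drawn from
a modular (block-structured) covariance, and the connectome is the sample
Pearson correlation of those T timepoints. Class structure is planted as
hypo-connectivity: class 1 reduces the correlation of one designated
inter-module block by ``effect`` (delta). One other inter-module block is
anti-correlated so the negative-sign branch of the model sees real edges.
Subject-level jitter perturbs the block correlation levels so subjects
within a class are not exchangeable copies.

What this does not emulate: hemodynamics, scanner/site effects, motion,
global signal artifacts — synthetic results bound what the architecture
can learn from clean modular structure, not performance on real cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .views import ConnectivitySample, ValidationError, save_matrix

_PSD_TOL = 1e-10


@dataclass
class SimConfig:
    """Cohort generator settings.

    ``modules`` are region-block sizes summing to N. ``base_corr`` is the
    within-module correlation; ``cross_corr`` the baseline correlation of
    the designated inter-module block (modules 1-2) that class 1 reduces
    by ``effect``; ``anti_corr`` the level of the anti-correlated block
    (modules 3-4, if present). ``noise_sd`` scales subject-level jitter of
    the block correlation levels.
    """

    N: int = 32
    T: int = 200
    n_per_class: int = 50
    modules: tuple[int, ...] = (8, 8, 8, 8)
    base_corr: float = 0.6
    effect: float = 0.3
    cross_corr: float = 0.4
    anti_corr: float = -0.2
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        self.modules = tuple(int(m) for m in self.modules)
        if sum(self.modules) != self.N:
            raise ValidationError(
                f"module sizes {self.modules} must sum to N={self.N}"
            )
        if self.T < 3:
            raise ValidationError("need at least 3 timepoints")
        for cls in (0, 1):
            c = target_correlation(self, cls)
            w = np.linalg.eigvalsh(c)
            if w.min() < _PSD_TOL:
                raise ValidationError(
                    f"class-{cls} target correlation is not positive "
                    f"semi-definite (min eigenvalue {w.min():.3g}); "
                    "reduce base_corr/cross_corr/effect"
                )


def _module_slices(modules: tuple[int, ...]) -> list[slice]:
    edges = np.cumsum((0,) + modules)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def target_correlation(cfg: SimConfig, cls: int,
                       jitter: np.ndarray | None = None) -> np.ndarray:
    """Population block-correlation matrix for one class.

    ``jitter`` perturbs the block levels: entry 0 shifts within-module
    correlation, 1 the designated cross block, 2 the anti block.
    """
    j = np.zeros(3) if jitter is None else jitter
    c = np.zeros((cfg.N, cfg.N))
    sl = _module_slices(cfg.modules)
    for s in sl:
        c[s, s] = cfg.base_corr + j[0]
    cross = cfg.cross_corr - (cfg.effect if cls == 1 else 0.0) + j[1]
    c[sl[0], sl[1]] = cross
    c[sl[1], sl[0]] = cross
    if len(sl) >= 4:
        anti = cfg.anti_corr + j[2]
        c[sl[2], sl[3]] = anti
        c[sl[3], sl[2]] = anti
    np.fill_diagonal(c, 1.0)
    return c


def simulate_subject(cls: int, cfg: SimConfig, subject_seed: int) -> ConnectivitySample:
    """Draw one subject: T Gaussian timepoints from the class covariance
    (with seeded subject jitter), then the sample Pearson correlation."""
    if cls not in (0, 1):
        raise ValidationError(f"class must be 0 or 1, got {cls}")
    rng = np.random.default_rng(subject_seed)
    cov = None
    for _ in range(10):
        jitter = rng.normal(0.0, cfg.noise_sd, size=3)
        cand = target_correlation(cfg, cls, jitter)
        if np.linalg.eigvalsh(cand).min() >= _PSD_TOL:
            cov = cand
            break
    if cov is None:
        raise ValidationError(
            "could not draw a positive semi-definite jittered covariance "
            "in 10 attempts; reduce noise_sd"
        )
    ts = rng.multivariate_normal(np.zeros(cfg.N), cov, size=cfg.T,
                                 method="cholesky")
    fc = np.corrcoef(ts, rowvar=False)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return ConnectivitySample(subject_id=f"sim-{cls}-{subject_seed}", fc=fc,
                              label=cls)


def subject_seed(cohort_seed: int, cls: int, index: int) -> int:
    """Deterministic per-subject seed derived from the cohort seed."""
    ss = np.random.SeedSequence((cohort_seed, cls, index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[list[ConnectivitySample], pd.DataFrame]:
    """Generate the full cohort; optionally write matrices + manifest.

    Returns the samples and a manifest frame (subject_id, path, label,
    subject_seed). With ``out_dir`` set, writes one CSV matrix per
    subject, ``manifest.tsv`` and a ``sim_config.json`` sidecar.
    """
    samples, rows = [], []
    for cls in (0, 1):
        for idx in range(cfg.n_per_class):
            seed = subject_seed(cfg.seed, cls, idx)
            s = simulate_subject(cls, cfg, seed)
            s.subject_id = f"sub-{cls}{idx:03d}"
            samples.append(s)
            rows.append({"subject_id": s.subject_id,
                         "path": f"{s.subject_id}.csv",
                         "label": cls, "subject_seed": seed})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(
                f"{out_dir} is not empty; pass overwrite=True to replace"
            )
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            save_matrix(out_dir / f"{s.subject_id}.csv", s.fc)
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        (out_dir / "sim_config.json").write_text(
            json.dumps(asdict(cfg), indent=2) + "\n")
    return samples, manifest
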