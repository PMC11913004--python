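import numpy as np
import pytest

from mvgat.model import ModelConfig
from mvgat.simulate import SimConfig, simulate_subject
from mvgat.views import ViewConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric_fc(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric correlation-like matrix with unit diagonal."""
    a = rng.uniform(-0.9, 0.9, size=(n, n))
    fc = (a + a.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return fc


@pytest.fixture
def tiny_model_config():
    """Small widths so forward/backward stay fast in unit tests."""
    return ModelConfig(V=3, n_regions=5, gat_hidden=6, gat_out=6,
                       te_dim=8, te_heads=2, view_head_hidden=4,
                       fusion_hidden=(8, 4), seed=7)


@pytest.fixture
def small_cohort():
    """A tiny simulated cohort (12 subjects, 16 regions)."""
    cfg = SimConfig(N=16, T=120, n_per_class=6, modules=(4, 4, 4, 4),
                    effect=0.4, seed=3)
    samples = []
    for cls in (0, 1):
        for i in range(cfg.n_per_class):
            s = simulate_subject(cls, cfg, 1000 + 17 * cls + i)
            s.subject_id = f"t-{cls}-{i}"
            samples.append(s)
    return samples


@pytest.fixture
def small_view_config():
    return ViewConfig(V=3, densities=(0.2, 0.4, 0.6))


from mvgat.diagnostics import finite_difference_max_rel_error  # noqa: E402,F401
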