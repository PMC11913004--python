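"""Numerical diagnostics: gradient verification against finite differences."""

from __future__ import annotations

import numpy as np

from .model import MVGATModel, total_loss


def finite_difference_max_rel_error(model: MVGATModel, batch, labels,
                                    aux_weight: float,
                                    entries_per_group: int = 2,
                                    eps: float = 1e-6) -> float:
    """Compare analytic gradients of the training loss against central
    differences, probing a few entries of every parameter group.

    ``batch`` is ``(pos, neg)`` in the :meth:`MVGATModel.forward_batch`
    layout. Returns the largest relative error
    ``max(|analytic - numeric| / max(1, |numeric|))`` over all probed
    entries.
    """
    pos, neg = batch
    labels = np.asarray(labels, dtype=int)

    def loss_value():
        fusion, per_view = model.forward_batch(pos, neg)
        return total_loss(fusion, per_view, labels, aux_weight)

    model.zero_grad()
    loss_value().backward()
    worst = 0.0
    for _, p in model.named_parameters().items():
        flat = p.data.reshape(-1)
        grad = (p.grad if p.grad is not None
                else np.zeros_like(p.data)).reshape(-1)
        step = max(1, flat.size // entries_per_group)
        for idx in range(0, flat.size, step):
            orig = flat[idx]
            flat[idx] = orig + eps
            fp = float(loss_value().data)
            flat[idx] = orig - eps
            fm = float(loss_value().data)
            flat[idx] = orig
            numeric = (fp - fm) / (2 * eps)
            rel = abs(grad[idx] - numeric) / max(1.0, abs(numeric))
            worst = max(worst, rel)
    return worst
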