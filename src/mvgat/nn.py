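"""Parameter containers and initialisation.

A :class:`Module` is a plain attribute bag: assigning a :class:`Tensor`
registers a parameter, assigning a Module (or list of Modules) registers a
child. ``named_parameters`` flattens the tree into ``path -> Tensor``,
which is the key scheme the checkpoint format and the optimizer use.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, add, matmul


class Module:
    def __setattr__(self, name, value):
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[path] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix=path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{path}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.named_parameters().values():
            p.zero_grad()


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Uniform Glorot/Xavier initialisation, seeded for determinism."""
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    """Affine map ``x @ W + b`` acting on the last axis."""

    def __init__(self, rng: np.random.Generator, in_features: int, out_features: int,
                 bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.W = glorot(rng, in_features, out_features)
        self.b = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.W)
        return add(y, self.b) if self.b is not None else y
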