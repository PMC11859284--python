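"""Neural-network building blocks on top of :mod:`clumm._autograd`.

Layers hold their parameters as :class:`~clumm._autograd.Tensor` objects with
``requires_grad=True``; ``Module.parameters()`` walks the tree so optimizers
and checkpoints can enumerate them deterministically.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, conv2d

__all__ = ["Module", "Linear", "ReLU", "Conv2d", "Sequential", "Residual"]


class Module:
    """Base class: children are discovered from instance attributes."""

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def _children(self):
        for name in sorted(vars(self)):
            value = getattr(self, name)
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for name in sorted(vars(self)):
            value = getattr(self, name)
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self._children():
            params.extend(child.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- flat state for checkpoints ------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    """Affine map ``x @ W + b`` with Kaiming-normal weight init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Residual(Module):
    """Skip connection: output = body(x) + shortcut(x).

    The identity shortcut realises the residual form phi = F(xi, W) + xi;
    when the body changes shape a projection shortcut is supplied.
    """

    def __init__(self, body: Module, shortcut: Module | None = None):
        self.body = body
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        skip = self.shortcut(x) if self.shortcut is not None else x
        return (self.body(x) + skip).relu()
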