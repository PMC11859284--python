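"""Adam-family optimizers and learning-rate schedules.

``Adam`` applies L2 regularisation through the gradient; ``AdamW`` decouples
weight decay from the adaptive moments. Schedules are plain callables
``epoch -> lr`` so training loops stay explicit.
"""

from __future__ import annotations

import math

import numpy as np

from ._autograd import Tensor

__all__ = ["Adam", "AdamW", "cosine_schedule", "multistep_schedule"]


class Adam:
    decoupled_weight_decay = False

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self._t
        bias2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decoupled_weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if self.weight_decay and self.decoupled_weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class AdamW(Adam):
    decoupled_weight_decay = True

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        super().__init__(params, lr=lr, betas=betas, eps=eps, weight_decay=weight_decay)


def cosine_schedule(base_lr: float, total_epochs: int):
    """Cosine decay from ``base_lr`` to 0 over ``total_epochs``."""

    def lr_at(epoch: int) -> float:
        frac = min(epoch, total_epochs) / max(total_epochs, 1)
        return base_lr * 0.5 * (1.0 + math.cos(math.pi * frac))

    return lr_at


def multistep_schedule(base_lr: float, milestones: tuple[int, ...] = (50, 75), gamma: float = 0.1):
    """Step decay: lr is multiplied by ``gamma`` at each milestone epoch."""

    milestones = tuple(sorted(milestones))

    def lr_at(epoch: int) -> float:
        drops = sum(1 for m in milestones if epoch >= m)
        return base_lr * gamma**drops

    return lr_at
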