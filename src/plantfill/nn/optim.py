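"""Optimizers: Adam with optional decoupled weight decay, plus StepLR."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW", "StepLR"]


class AdamW:
    """Adaptive-moments optimizer.

    ``decoupled=True`` (default) applies weight decay directly to the
    parameters (AdamW); ``decoupled=False`` folds the decay into the
    gradient (classical Adam with L2).
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
        decoupled: bool = True,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if not self.decoupled and self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.decoupled and self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update


class StepLR:
    """Multiply the optimizer's learning rate by ``gamma`` every ``step_size`` steps."""

    def __init__(self, optimizer: AdamW, step_size: int = 50, gamma: float = 0.5):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self.count = 0

    def step(self) -> None:
        self.count += 1
        if self.count % self.step_size == 0:
            self.optimizer.lr *= self.gamma
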