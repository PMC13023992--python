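"""Adam optimiser with cosine-annealed learning rate."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "CosineAnnealingLR"]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


class CosineAnnealingLR:
    """Anneal the optimiser's lr from its initial value to ``eta_min`` over
    ``t_max`` epochs following a half cosine."""

    def __init__(self, optimizer: Adam, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.t_max = max(t_max, 1)
        self.eta_min = eta_min
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self) -> None:
        self.epoch = min(self.epoch + 1, self.t_max)
        frac = 0.5 * (1.0 + math.cos(math.pi * self.epoch / self.t_max))
        self.optimizer.lr = self.eta_min + (self.base_lr - self.eta_min) * frac

    @property
    def lr(self) -> float:
        return self.optimizer.lr
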