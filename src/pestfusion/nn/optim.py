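"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "SGD", "cosine_annealing_lr"]


def cosine_annealing_lr(epoch: int, lr0: float, t_max: int,
                        lr_min: float = 0.0) -> float:
    """Cosine annealing: ``lr0`` at epoch 0, ``lr_min`` at epoch ``t_max``."""
    if t_max <= 0:
        return lr0
    e = min(epoch, t_max)
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * e / t_max))


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2)
                                                    + self.eps)
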