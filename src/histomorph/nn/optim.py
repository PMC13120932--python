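"""Optimisation utilities: AdamW, cosine-annealed learning rate, gradient clipping."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter

__all__ = ["AdamW", "SGD", "cosine_lr", "clip_grad_norm"]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data  # decoupled decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class SGD:
    """Plain SGD (optionally with momentum); accepted as an alternative optimizer name."""

    def __init__(self, params: list[Parameter], lr: float = 1e-2,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(initial_lr: float, epoch: int, total_epochs: int, min_lr: float = 0.0) -> float:
    """Cosine annealing: lr(0) = initial_lr, decaying to `min_lr` at the last epoch."""
    if total_epochs <= 1:
        return initial_lr
    frac = epoch / (total_epochs - 1)
    return min_lr + 0.5 * (initial_lr - min_lr) * (1.0 + math.cos(math.pi * frac))


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most `max_norm`; returns pre-clip norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
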