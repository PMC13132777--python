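"""Adam optimizer, gradient clipping, and the cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "clip_grad_norm", "cosine_lr"]


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None or not p.requires_grad:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g.astype(np.float64) ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale
    return norm


def cosine_lr(epoch: int, total_epochs: int, lr_init: float, lr_min: float,
              restart_period: int | None = None) -> float:
    """Cosine annealing from ``lr_init`` to ``lr_min``.

    Without restarts the annealing spans ``total_epochs``; with
    ``restart_period`` the cosine cycle restarts from ``lr_init`` every that
    many epochs (warm restarts).
    """
    if restart_period:
        t = epoch % restart_period
        span = restart_period
    else:
        t = epoch
        span = max(total_epochs, 1)
    frac = min(t / span, 1.0)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + math.cos(math.pi * frac))
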