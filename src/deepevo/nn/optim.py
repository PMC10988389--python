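"""Adam optimizer and the exponential learning-rate interpolation used by the
generator training schedule."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, grad


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, grads: list[Tensor]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data
            m *= self.b1
            m += (1.0 - self.b1) * gd
            v *= self.b2
            v += (1.0 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def exp_lr(step: int, total_steps: int, lr_start: float, lr_end: float) -> float:
    """Per-step exponential interpolation from lr_start to lr_end."""
    if total_steps <= 1:
        return lr_start
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return lr_start * math.exp(frac * math.log(lr_end / lr_start))


def backward(loss, params, create_graph: bool = False):
    """Convenience wrapper: gradients of a scalar loss w.r.t. params."""
    return grad(loss, params, create_graph=create_graph)
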