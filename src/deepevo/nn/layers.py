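"""Network building blocks: dense, 1-D convolution, residual conv blocks and
multi-head self-attention, assembled by the selector and the generator/
discriminator pair."""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class; parameters are discovered recursively by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint has wrong number of arrays")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)

    def cast(self, dtype) -> None:
        for p in self.parameters():
            p.data = p.data.astype(dtype)


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_he_init(rng, n_in, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padded 1-D convolution on (B, C, L), via unfold + matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.c_in = c_in
        self.weight = Tensor(_he_init(rng, c_in * kernel, (c_in * kernel, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        cols = ag.unfold1d(x, self.kernel, self.kernel // 2)  # (B, L, C*K)
        out = cols @ self.weight + self.bias                  # (B, L, C_out)
        return out.transpose(0, 2, 1)                         # (B, C_out, L)


class ResBlock1d(Module):
    """Residual block of 3 same-padded convolutions with ReLU activations."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.convs = [Conv1d(channels, channels, kernel, rng) for _ in range(3)]

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i, conv in enumerate(self.convs):
            h = conv(ag.relu(h)) if i else conv(h)
        return x + ag.relu(h) * 0.3  # damped residual branch for stability


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the length axis of (B, C, L).

    With ``pool`` > 1 the attention operates on average-pooled positions
    (window ``pool``) and its output is broadcast back before the residual
    add — attention at reduced spatial resolution, as is usual for
    convolutional sequence GANs, cutting the L x L cost by pool^2.
    """

    def __init__(self, channels: int, n_heads: int, rng: np.random.Generator,
                 pool: int = 1):
        if channels % n_heads:
            raise ValueError(
                f"channels ({channels}) must be divisible by heads ({n_heads})")
        self.n_heads = n_heads
        self.d_head = channels // n_heads
        self.pool = pool
        self.q = Dense(channels, channels, rng)
        self.k = Dense(channels, channels, rng)
        self.v = Dense(channels, channels, rng)
        self.out = Dense(channels, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, l = x.shape
        p = self.pool
        if l % p:
            raise ValueError(f"length {l} not divisible by attention pool {p}")
        lp = l // p
        if p > 1:
            h = x.reshape(b, c, lp, p).mean(axis=3).transpose(0, 2, 1)
        else:
            h = x.transpose(0, 2, 1)  # (B, L, C)

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, lp, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(h)), split(self.k(h)), split(self.v(h))
        att = ag.softmax(q @ k.transpose(0, 1, 3, 2) * (1.0 / math.sqrt(self.d_head)),
                         axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(b, lp, self.n_heads * self.d_head)
        y = self.out(ctx).transpose(0, 2, 1)  # (B, C, Lp)
        if p > 1:
            y = ag.broadcast_to(y.reshape(b, c, lp, 1), (b, c, lp, p)
                                ).reshape(b, c, l)
        return x + y


class MLP(Module):
    """Fully connected classifier trunk: dims[0] -> ... -> dims[-1] with ReLU
    between layers and a raw final output (the caller applies sigmoid)."""

    def __init__(self, dims, rng: np.random.Generator):
        self.layers = [Dense(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = ag.relu(layer(x))
        return self.layers[-1](x)
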