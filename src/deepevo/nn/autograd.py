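"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine exists because the generator/discriminator training objective
includes a gradient penalty: the penalty is a function of the gradient of the
discriminator with respect to its *input*, and its own gradient with respect
to the discriminator *weights* is needed for the update.  Every primitive
therefore implements its vector-Jacobian product in terms of other
primitives, so that gradients are themselves differentiable graph nodes
(``grad(..., create_graph=True)``).

Only the operations required by the sequence models are provided: elementwise
arithmetic, (batched) matmul, relu/sigmoid/softplus/softmax, reductions,
shape manipulation, and an unfold/fold pair from which 1-D convolution is
composed.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "tensor", "grad", "default_dtype"]

_DEFAULT_DTYPE = np.float64


@contextmanager
def default_dtype(dt):
    """Temporarily change the dtype new tensors are created with.

    float64 is the default (gradient-check accuracy); GAN training runs
    under float32 for speed.
    """
    global _DEFAULT_DTYPE
    old = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = dt
    try:
        yield
    finally:
        _DEFAULT_DTYPE = old


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(self, data, parents=(), vjp=None, requires_grad=False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.parents = parents
        self.vjp = vjp
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return self.data.item()

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad=False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum a broadcast gradient back down to ``shape`` (graph-preserving)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# -- arithmetic ------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, (a, b))
    out.vjp = lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, (a, b))
    out.vjp = lambda g: (_unbroadcast(mul(g, b), a.shape),
                         _unbroadcast(mul(g, a), b.shape))
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data ** exponent, (a,))
    out.vjp = lambda g: (mul(g, mul(power(a, exponent - 1.0), _wrap(exponent))),)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, (a, b))

    def vjp(g):
        ga = matmul(g, _swap_last(b))
        gb = matmul(_swap_last(a), g)
        return (_unbroadcast_matmul(ga, a.shape), _unbroadcast_matmul(gb, b.shape))

    out.vjp = vjp
    return out


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(t, tuple(axes))


def _unbroadcast_matmul(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i in range(len(shape) - 2) if shape[i] == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# -- nonlinearities --------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = (a.data > 0).astype(a.data.dtype)
    out = Tensor(np.maximum(a.data, 0), (a,))
    out.vjp = lambda g: (mul(g, _wrap(mask)),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = Tensor(_sigmoid(a.data), (a,))
    out.vjp = lambda g: (mul(g, mul(out, 1.0 - out)),)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable in both tails
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)), stable; note -log(sigmoid(x)) == softplus(-x)."""
    a = _wrap(a)
    x = a.data
    out = Tensor(np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x))), (a,))
    out.vjp = lambda g: (mul(g, sigmoid(a)),)
    return out


def exp(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.exp(a.data), (a,))
    out.vjp = lambda g: (mul(g, exp(a)),)
    return out


def log(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.log(a.data), (a,))
    out.vjp = lambda g: (mul(g, power(a, -1.0)),)
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, (a,))

    def vjp(g):
        inner = tsum(mul(g, out), axis=axis, keepdims=True)
        return (mul(out, g - inner),)

    out.vjp = vjp
    return out


# -- reductions and shape --------------------------------------------------

def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.broadcast_to(a.data, shape), (a,))
    out.vjp = lambda g: (_unbroadcast(g, a.shape),)
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def vjp(g):
        if axis is None:
            return (broadcast_to(g, a.shape),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % a.ndim for ax in axes)
        if not keepdims:
            full = list(g.shape)
            for ax in sorted(axes):
                full.insert(ax, 1)
            g = reshape(g, tuple(full))
        return (broadcast_to(g, a.shape),)

    out.vjp = vjp
    return out


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax % a.ndim] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a: Tensor, shape: tuple) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), (a,))
    out.vjp = lambda g: (reshape(g, a.shape),)
    return out


def transpose(a: Tensor, axes=None) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.transpose(axes), (a,))
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    out.vjp = lambda g: (transpose(g, inv),)
    return out


# -- unfold / fold (the linear pair behind 1-D convolution) ---------------

def unfold1d(a: Tensor, kernel: int, pad: int) -> Tensor:
    """(B, C, L) -> (B, L, C*kernel) sliding windows with zero padding."""
    a = _wrap(a)
    out = Tensor(_unfold_np(a.data, kernel, pad), (a,))
    out.vjp = lambda g: (fold1d(g, a.shape[1], a.shape[2], kernel, pad),)
    return out


def fold1d(a: Tensor, channels: int, length: int, kernel: int, pad: int) -> Tensor:
    """Adjoint of :func:`unfold1d`: (B, L, C*kernel) -> (B, C, L)."""
    a = _wrap(a)
    out = Tensor(_fold_np(a.data, channels, length, kernel, pad), (a,))
    out.vjp = lambda g: (unfold1d(g, kernel, pad),)
    return out


def _unfold_np(x: np.ndarray, kernel: int, pad: int) -> np.ndarray:
    b, c, l = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)
    # win: (B, C, L_out, K) with L_out = l + 2*pad - kernel + 1
    return win.transpose(0, 2, 1, 3).reshape(b, win.shape[2], c * kernel)


def _fold_np(g: np.ndarray, channels: int, length: int, kernel: int, pad: int) -> np.ndarray:
    b, l_out, _ = g.shape
    gk = g.reshape(b, l_out, channels, kernel)
    out = np.zeros((b, channels, length + 2 * pad), dtype=g.dtype)
    for k in range(kernel):
        out[:, :, k:k + l_out] += gk[:, :, :, k].transpose(0, 2, 1)
    return out[:, :, pad:pad + length] if pad else out


# -- backward pass ---------------------------------------------------------

def _topo(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph and
    can be differentiated again (used by the R1 penalty).
    """
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")
    keep = {id(t) for t in inputs}
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape))}
    for node in reversed(_topo(output)):
        g = grads.get(id(node))
        if g is None:
            continue
        if id(node) not in keep:
            del grads[id(node)]
        if node.vjp is None:
            continue
        if not create_graph:
            g = g.detach()
        for parent, pg in zip(node.parents, node.vjp(g)):
            if pg is None or not parent.requires_grad:
                continue
            held = grads.get(id(parent))
            grads[id(parent)] = pg if held is None else add(held, pg)
    out = []
    for t in inputs:
        gt = grads.get(id(t))
        if gt is None:
            gt = Tensor(np.zeros(t.shape))
        out.append(gt)
    return out
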