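"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides the handful of differentiable primitives the
segmentation networks in this package are composed of: elementwise
arithmetic with broadcasting, reductions, 2-D convolutions (standard and
depthwise, stride 1, "same" padding), 2x2 max-pooling, nearest-neighbour
upsampling, channel concatenation, dropout and the usual activations.

Gradients are exact vector-Jacobian products, accumulated by a
topological-order backward sweep; every primitive is validated against
central finite differences in the test suite.  The engine is deliberately
small: no graphs survive past ``backward()``, no higher-order derivatives,
float64 throughout (CPU-scale models make the extra precision cheap and
keep gradient checks tight).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "sqrt", "clip",
    "relu", "sigmoid", "softmax",
    "sum_", "mean_", "reshape", "concat",
    "conv2d", "depthwise_conv2d", "maxpool2x2", "upsample2x2", "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp", "name")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, value, requires_grad=False, _parents=(), _vjp=None,
                 name=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._vjp = _vjp
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without an explicit seed "
                                 "requires a scalar output")
            grad = np.ones_like(self.value)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep U-Nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._vjp(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
# elementwise arithmetic
# ----------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.value + b.value
    return Tensor(out, _parents=(a, b),
                  _vjp=lambda g: (_unbroadcast(g, a.shape),
                                  _unbroadcast(g, b.shape)))


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.value - b.value
    return Tensor(out, _parents=(a, b),
                  _vjp=lambda g: (_unbroadcast(g, a.shape),
                                  _unbroadcast(-g, b.shape)))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.value * b.value
    return Tensor(out, _parents=(a, b),
                  _vjp=lambda g: (_unbroadcast(g * b.value, a.shape),
                                  _unbroadcast(g * a.value, b.shape)))


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.value / b.value
    return Tensor(out, _parents=(a, b),
                  _vjp=lambda g: (
                      _unbroadcast(g / b.value, a.shape),
                      _unbroadcast(-g * a.value / (b.value ** 2), b.shape)))


def neg(a):
    a = as_tensor(a)
    return Tensor(-a.value, _parents=(a,), _vjp=lambda g: (-g,))


def power(a, p: float):
    a = as_tensor(a)
    out = a.value ** p
    return Tensor(out, _parents=(a,),
                  _vjp=lambda g: (g * p * a.value ** (p - 1),))


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.value)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * 0.5 / out,))


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.value)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out,))


def log(a):
    a = as_tensor(a)
    return Tensor(np.log(a.value), _parents=(a,),
                  _vjp=lambda g: (g / a.value,))


def clip(a, lo: float, hi: float):
    """Clamp to [lo, hi]; gradient passes only where the input is inside."""
    a = as_tensor(a)
    out = np.clip(a.value, lo, hi)
    inside = (a.value > lo) & (a.value < hi)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * inside,))


# ----------------------------------------------------------------------
# activations
# ----------------------------------------------------------------------

def relu(a):
    a = as_tensor(a)
    mask = a.value > 0
    return Tensor(a.value * mask, _parents=(a,), _vjp=lambda g: (g * mask,))


def sigmoid(a):
    a = as_tensor(a)
    x = a.value
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out * (1 - out),))


def softmax(a):
    """Softmax over the last axis."""
    a = as_tensor(a)
    z = a.value - a.value.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=-1, keepdims=True)

    def vjp(g):
        dot = (g * out).sum(axis=-1, keepdims=True)
        return (out * (g - dot),)

    return Tensor(out, _parents=(a,), _vjp=vjp)


# ----------------------------------------------------------------------
# reductions & shape ops
# ----------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, [ax % a.ndim for ax in axes])
        return (np.broadcast_to(g, a.shape).copy(),)

    return Tensor(out, _parents=(a,), _vjp=vjp)


def mean_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        count = a.value.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return sum_(a, axis=axis, keepdims=keepdims) * (1.0 / count)


def reshape(a, shape):
    a = as_tensor(a)
    return Tensor(a.value.reshape(shape), _parents=(a,),
                  _vjp=lambda g: (g.reshape(a.shape),))


def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, _parents=tuple(tensors), _vjp=vjp)


# ----------------------------------------------------------------------
# convolutions (NHWC, stride 1, "same" padding)
# ----------------------------------------------------------------------

def _same_pad(kh: int, kw: int):
    # TensorFlow "same" convention: extra pixel goes to bottom/right
    t = (kh - 1) // 2
    l = (kw - 1) // 2
    return t, kh - 1 - t, l, kw - 1 - l


def conv2d(x, w, b=None):
    """Standard 2-D convolution (cross-correlation), stride 1, same padding.

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    kh, kw, cin, cout = w.shape
    n, h, wd, cx = x.shape
    if cx != cin:
        raise ValueError(f"channel mismatch: input has {cx}, kernel expects {cin}")
    pt, pb, pl, pr = _same_pad(kh, kw)
    xp = np.pad(x.value, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    out = np.zeros((n, h, wd, cout))
    for i in range(kh):
        for j in range(kw):
            out += np.tensordot(xp[:, i:i + h, j:j + wd, :], w.value[i, j],
                                axes=([3], [0]))

    def vjp(g):
        dw = np.empty_like(w.value)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i:i + h, j:j + wd, :]
                dw[i, j] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i:i + h, j:j + wd, :] += np.tensordot(
                    g, w.value[i, j], axes=([3], [1]))
        dx = dxp[:, pt:pt + h, pl:pl + wd, :]
        return dx, dw

    out_t = Tensor(out, _parents=(x, w), _vjp=vjp)
    if b is not None:
        out_t = out_t + as_tensor(b)
    return out_t


def depthwise_conv2d(x, w):
    """Depthwise 2-D convolution: each channel with its own k x k filter.

    x: (N, H, W, C); w: (kh, kw, C) or (kh, kw, C, 1).  No bias (the
    pointwise stage that follows carries one).
    """
    x, w = as_tensor(x), as_tensor(w)
    wv = w.value
    squeeze = wv.ndim == 4
    if squeeze:
        if wv.shape[3] != 1:
            raise ValueError("depthwise channel multiplier must be 1")
        wv = wv[..., 0]
    kh, kw, c = wv.shape
    n, h, wd, cx = x.shape
    if cx != c:
        raise ValueError(f"channel mismatch: input has {cx}, kernel expects {c}")
    pt, pb, pl, pr = _same_pad(kh, kw)
    xp = np.pad(x.value, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    out = np.zeros((n, h, wd, c))
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i:i + h, j:j + wd, :] * wv[i, j]

    def vjp(g):
        dw = np.empty_like(wv)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dw[i, j] = (xp[:, i:i + h, j:j + wd, :] * g).sum(axis=(0, 1, 2))
                dxp[:, i:i + h, j:j + wd, :] += g * wv[i, j]
        dx = dxp[:, pt:pt + h, pl:pl + wd, :]
        if squeeze:
            dw = dw[..., None]
        return dx, dw

    return Tensor(out, _parents=(x, w), _vjp=vjp)


# ----------------------------------------------------------------------
# pooling / resizing / regularization
# ----------------------------------------------------------------------

def maxpool2x2(x):
    """2x2 max pooling, stride 2.  Ties route gradient to the first max."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    xr = x.value.reshape(n, h // 2, 2, w // 2, 2, c)
    xw = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        gw = np.zeros((n, h // 2, w // 2, c, 4))
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(n, h // 2, w // 2, c, 2, 2).transpose(
            0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        return (gx,)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def upsample2x2(x):
    """Nearest-neighbour x2 upsampling (parameter-free)."""
    x = as_tensor(x)
    out = np.repeat(np.repeat(x.value, 2, axis=1), 2, axis=2)
    n, h, w, c = x.shape

    def vjp(g):
        return (g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)),)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def dropout(x, rate: float, rng: np.random.Generator, training: bool = True):
    """Inverted dropout; identity when not training or rate == 0."""
    x = as_tensor(x)
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return Tensor(x.value * mask, _parents=(x,), _vjp=lambda g: (g * mask,))
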