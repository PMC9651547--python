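"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the resulting tape in reverse topological
order and accumulates gradients.  Only the operations needed by the network
are provided, each with a hand-derived adjoint; fused kernels (softmax,
layer norm, convolutions, cross-entropy) keep the tape short and fast.

All arithmetic is float64 by default for gradient-check fidelity; training
code may pass float32 arrays and everything follows the input dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "reshape", "transpose", "mean", "total",
    "relu", "gelu", "softmax", "layer_norm",
    "conv2d", "depthwise_conv2d", "maxpool2d", "batch_norm2d",
    "cross_entropy",
]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node; ``grad`` defaults to ones."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(old))

    return Tensor._make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = a.data.transpose(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return Tensor._make(out_data, (a,), backward)


def mean(a, axis, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    n = int(np.prod([a.data.shape[ax] for ax in axis]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g / n, a.data.shape).copy())

    return Tensor._make(out_data, (a,), backward)


def total(a) -> Tensor:
    """Sum of all elements (scalar)."""
    a = _as_tensor(a)
    out_data = a.data.sum()

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return Tensor._make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return Tensor._make(out_data, (a,), backward)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(a) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    a = _as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def backward(g):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
        da = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
        a._accumulate(g * da)

    return Tensor._make(out_data, (a,), backward)


def softmax(a) -> Tensor:
    """Softmax along the last axis."""
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        a._accumulate(y * (g - dot))

    return Tensor._make(y, (a,), backward)


def layer_norm(a, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    a, gamma, beta = _as_tensor(a), _as_tensor(gamma), _as_tensor(beta)
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out_data = xhat * gamma.data + beta.data
    n = a.data.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, n).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, n).sum(axis=0))
        if a.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(inv * (gy - m1 - xhat * m2))

    return Tensor._make(out_data, (a, gamma, beta), backward)


# ---------------------------------------------------------------------------
# convolutions and pooling (NHWC layout)
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, pad: int, value: float = 0.0) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)),
                  constant_values=value)


def conv2d(x, w, b, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, ``x`` (B,H,W,Cin), ``w`` (kh,kw,Cin,Cout), ``b`` (Cout,)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, H, W, Ci = x.data.shape
    kh, kw, Ci2, Co = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"conv2d channel mismatch: input has {Ci}, weight expects {Ci2}")
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    xp = _pad_hw(x.data, padding)
    out_data = np.zeros((B, Ho, Wo, Co), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, i:i + stride * Ho:stride, j:j + stride * Wo:stride, :]
            out_data += xs @ w.data[i, j]
    out_data += b.data

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(i, i + stride * Ho, stride),
                      slice(j, j + stride * Wo, stride), slice(None))
                if w.requires_grad:
                    gw = np.tensordot(xp[sl], g, axes=([0, 1, 2], [0, 1, 2]))
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[i, j] += gw
                if dxp is not None:
                    dxp[sl] += g @ w.data[i, j].T
        if dxp is not None:
            if padding:
                dxp = dxp[:, padding:padding + H, padding:padding + W, :]
            x._accumulate(dxp)

    return Tensor._make(out_data, (x, w, b), backward)


def depthwise_conv2d(x, w, b, stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise 2-D convolution, ``w`` (kh,kw,C): one filter per channel."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, H, W, C = x.data.shape
    kh, kw, C2 = w.data.shape
    if C != C2:
        raise ValueError(f"depthwise channel mismatch: input has {C}, weight expects {C2}")
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    xp = _pad_hw(x.data, padding)
    out_data = np.zeros((B, Ho, Wo, C), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, i:i + stride * Ho:stride, j:j + stride * Wo:stride, :]
            out_data += xs * w.data[i, j]
    out_data += b.data

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(i, i + stride * Ho, stride),
                      slice(j, j + stride * Wo, stride), slice(None))
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[i, j] += (xp[sl] * g).sum(axis=(0, 1, 2))
                if dxp is not None:
                    dxp[sl] += g * w.data[i, j]
        if dxp is not None:
            if padding:
                dxp = dxp[:, padding:padding + H, padding:padding + W, :]
            x._accumulate(dxp)

    return Tensor._make(out_data, (x, w, b), backward)


def maxpool2d(x, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling over NHWC spatial windows; padded cells never win."""
    x = _as_tensor(x)
    B, H, W, C = x.data.shape
    Ho = (H + 2 * padding - kernel) // stride + 1
    Wo = (W + 2 * padding - kernel) // stride + 1
    xp = _pad_hw(x.data, padding, value=-np.inf)
    slices = []
    for i in range(kernel):
        for j in range(kernel):
            slices.append(xp[:, i:i + stride * Ho:stride, j:j + stride * Wo:stride, :])
    stack = np.stack(slices)                       # (k*k, B, Ho, Wo, C)
    arg = stack.argmax(axis=0)
    out_data = stack.max(axis=0)

    def backward(g):
        dxp = np.zeros((B, H + 2 * padding, W + 2 * padding, C), dtype=g.dtype)
        k = 0
        for i in range(kernel):
            for j in range(kernel):
                sl = (slice(None), slice(i, i + stride * Ho, stride),
                      slice(j, j + stride * Wo, stride), slice(None))
                dxp[sl] += g * (arg == k)
                k += 1
        if padding:
            dxp = dxp[:, padding:padding + H, padding:padding + W, :]
        x._accumulate(dxp)

    return Tensor._make(out_data, (x,), backward)


def batch_norm2d(x, gamma, beta, running_mean, running_var,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (B,H,W) of an NHWC map.

    ``running_mean``/``running_var`` are plain ndarrays updated in place when
    ``training`` is true.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    if training:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gy = g * gamma.data
            if training:
                m1 = gy.mean(axis=(0, 1, 2))
                m2 = (gy * xhat).mean(axis=(0, 1, 2))
                x._accumulate(inv * (gy - m1 - xhat * m2))
            else:
                x._accumulate(inv * gy)

    return Tensor._make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_entropy(logits, labels) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row-wise softmax of ``logits``."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    picked = z[np.arange(len(labels)), labels]
    out_data = np.mean(lse - picked)

    def backward(g):
        p = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
        p[np.arange(len(labels)), labels] -= 1.0
        logits._accumulate(g * p / len(labels))

    return Tensor._make(out_data, (logits,), backward)
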