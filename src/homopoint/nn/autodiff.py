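"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the homologous
point network needs: broadcast arithmetic, (batched) matmul, reshape /
transpose, reductions, softmax, GELU, layer normalization, slicing and row
gather.  Gradients are accumulated into ``Tensor.grad`` by ``backward()`` on
a scalar output.

Design notes: arrays are float64 throughout (CPU-only workloads here are
small and exactness simplifies testing); convolutions are composed from
slice + matmul primitives by the layer code rather than being primitives
themselves.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "add", "mul", "matmul", "reshape", "transpose", "tsum", "tmean",
           "softmax", "gelu", "layer_norm", "tslice", "gather_rows", "tabs", "concat"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor/tensor division not supported; multiply by a reciprocal")
        return mul(self, _wrap(1.0 / scalar))

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    # autodiff -------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g)  # defensive copy; g may be a shared buffer
        else:
            self.grad += g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            if b.data.ndim == 2 and a.data.ndim > 2:
                # shared weight across a batch: single flat GEMM
                k = a.data.shape[-1]
                gb = a.data.reshape(-1, k).T @ g.reshape(-1, g.shape[-1])
                b.accumulate(gb)
            else:
                b.accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape[0]) if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else tuple(shape)
    out_data = a.data.reshape(shape)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g.reshape(a.shape))

    return Tensor(out_data, parents=(a,), backward=bwd)


def transpose(a: Tensor, axes=None) -> Tensor:
    out_data = a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g.transpose(inv))

    return Tensor(out_data, parents=(a,), backward=bwd)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not a.requires_grad:
            return
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            a.accumulate(np.broadcast_to(gg, a.shape).copy())

    return Tensor(out_data, parents=(a,), backward=bwd)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), _wrap(1.0 / n))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a.accumulate(s * (g - dot))

    return Tensor(s, parents=(a,), backward=bwd)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) GELU."""
    x = a.data
    phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out_data = x * phi

    def bwd(g):
        if a.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
            a.accumulate(g * (phi + x * pdf))

    return Tensor(out_data, parents=(a,), backward=bwd)


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    n = x.shape[-1]

    def bwd(g):
        if gamma.requires_grad:
            gamma.accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta.accumulate(_unbroadcast(g, beta.shape))
        if a.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            a.accumulate(term * inv)

    return Tensor(out_data, parents=(a, gamma, beta), backward=bwd)


def tslice(a: Tensor, key) -> Tensor:
    out_data = a.data[key]

    def bwd(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            buf[key] = g
            a.accumulate(buf)

    return Tensor(out_data, parents=(a,), backward=bwd)


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def bwd(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a.accumulate(buf)

    return Tensor(out_data, parents=(a,), backward=bwd)


def tabs(a: Tensor) -> Tensor:
    out_data = np.abs(a.data)
    sign = np.sign(a.data)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * sign)

    return Tensor(out_data, parents=(a,), backward=bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)
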