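"""A compact reverse-mode autograd engine over numpy arrays.

Supports exactly the operations the detector needs: broadcasted arithmetic,
sigmoid/SiLU/exp/log/sqrt/atan, elementwise max/min, reductions, reshapes,
slicing, concatenation, im2col 2-D convolution, max pooling and
nearest-neighbor upsampling. Gradients flow through a dynamically built tape;
``Tensor.backward()`` runs a topological sweep.

float32 is used throughout for speed; gradient buffers are float32 too.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum out broadcast axes so ``grad`` matches ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(out):
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        out = Tensor._make(out_data, (self, other), None)
        out._backward = lambda: backward(out)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def backward():
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def backward():
            self._accum(_unbroadcast(out.grad / other.data, self.shape))
            other._accum(
                _unbroadcast(-out.grad * self.data / (other.data**2), other.shape)
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data**p, (self,), None)
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    # -- nonlinearities -------------------------------------------------------

    def exp(self):
        out = Tensor._make(np.exp(self.data), (self,), None)
        out._backward = lambda: self._accum(out.grad * out.data)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def sqrt(self):
        out = Tensor._make(np.sqrt(self.data), (self,), None)
        out._backward = lambda: self._accum(out.grad * 0.5 / np.maximum(out.data, 1e-12))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(s, (self,), None)
        out._backward = lambda: self._accum(out.grad * out.data * (1.0 - out.data))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(self.data * s, (self,), None)

        def backward():
            self._accum(out.grad * (s + self.data * s * (1.0 - s)))

        out._backward = backward
        return out

    def atan(self):
        out = Tensor._make(np.arctan(self.data), (self,), None)
        out._backward = lambda: self._accum(out.grad / (1.0 + self.data**2))
        return out

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(np.maximum(self.data, other.data), (self, other), None)

        def backward():
            mask = (self.data >= other.data).astype(np.float32)
            self._accum(_unbroadcast(out.grad * mask, self.shape))
            other._accum(_unbroadcast(out.grad * (1.0 - mask), other.shape))

        out._backward = backward
        return out

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(np.minimum(self.data, other.data), (self, other), None)

        def backward():
            mask = (self.data <= other.data).astype(np.float32)
            self._accum(_unbroadcast(out.grad * mask, self.shape))
            other._accum(_unbroadcast(out.grad * (1.0 - mask), other.shape))

        out._backward = backward
        return out

    def clamp_min(self, lo: float):
        out = Tensor._make(np.maximum(self.data, lo), (self,), None)

        def backward():
            self._accum(out.grad * (self.data >= lo).astype(np.float32))

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else axis
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in ((axis,) if isinstance(axis, int) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape
        out = Tensor._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda: self._accum(out.grad.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(*axes), (self,), None)
        out._backward = lambda: self._accum(out.grad.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def backward():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)  # duplicates in fancy indices accumulate
            self._accum(g)

        out._backward = backward
        return out

    # -- spatial ops ----------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: Optional["Tensor"] = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution via im2col. weight shape (Cout, Cin, K, K)."""
        x = self.data
        w = weight.data
        n, cin, h, wdt = x.shape
        cout, _, kh, kw = w.shape
        ho = (h + 2 * padding - kh) // stride + 1
        wo = (wdt + 2 * padding - kw) // stride + 1
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        cols = _im2col(xp, kh, kw, stride, ho, wo)  # (N, Cin*K*K, Ho*Wo)
        wm = w.reshape(cout, -1)  # (Cout, Cin*K*K)
        out_data = np.einsum("ok,nkp->nop", wm, cols, optimize=True)
        out_data = out_data.reshape(n, cout, ho, wo)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, cout, 1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor._make(out_data, parents, None)

        def backward():
            go = out.grad.reshape(n, cout, ho * wo)
            if weight.requires_grad:
                gw = np.einsum("nop,nkp->ok", go, cols, optimize=True)
                weight._accum(gw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(go.sum(axis=(0, 2)))
            if self.requires_grad:
                gcols = np.einsum("ok,nop->nkp", wm, go, optimize=True)
                gx = _col2im(gcols, xp.shape, kh, kw, stride, ho, wo)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self._accum(gx)

        out._backward = backward
        return out

    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0):
        x = self.data
        n, c, h, w = x.shape
        ho = (h + 2 * padding - kernel) // stride + 1
        wo = (w + 2 * padding - kernel) // stride + 1
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf) if padding else x
        cols = _im2col(xp.reshape(n * c, 1, *xp.shape[2:]), kernel, kernel, stride, ho, wo)
        cols = cols.reshape(n * c, kernel * kernel, ho * wo)
        arg = cols.argmax(axis=1)  # (N*C, Ho*Wo)
        out_data = np.take_along_axis(cols, arg[:, None, :], axis=1)[:, 0, :]
        out = Tensor._make(out_data.reshape(n, c, ho, wo), (self,), None)

        def backward():
            go = out.grad.reshape(n * c, ho * wo)
            gcols = np.zeros((n * c, kernel * kernel, ho * wo), dtype=np.float32)
            np.put_along_axis(gcols, arg[:, None, :], go[:, None, :], axis=1)
            gx = _col2im(gcols, (n * c, 1, *xp.shape[2:]), kernel, kernel, stride, ho, wo)
            gx = gx.reshape(n, c, *xp.shape[2:])
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            self._accum(gx)

        out._backward = backward
        return out

    def upsample2x(self):
        """Nearest-neighbor 2x spatial upsampling."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)
        out = Tensor._make(out_data, (self,), None)

        def backward():
            n, c, h2, w2 = out.grad.shape
            g = out.grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            self._accum(g)

        out._backward = backward
        return out

    # -- backward sweep -------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise RuntimeError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
                # free tape memory as we go
                node._backward = None
                node._prev = ()


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor._make(np.concatenate(datas, axis=axis), tensors, None)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(sl)])

    out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, ho*wo) patch matrix."""
    n, c = x.shape[:2]
    s0, s1, s2, s3 = x.strides
    shape = (n, c, kh, kw, ho, wo)
    strides = (s0, s1, s2, s3, s2 * stride, s3 * stride)
    patches = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return np.ascontiguousarray(patches).reshape(n, c * kh * kw, ho * wo)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int,
            stride: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to image layout."""
    n, c, h, w = x_shape
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    gx = np.zeros((n, c, h, w), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    return gx
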