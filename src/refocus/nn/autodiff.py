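"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine providing exactly the operations the
refocusing network needs: broadcasted arithmetic, the usual pointwise
nonlinearities, axis reductions, dense and 2D convolution layers (stride 1,
zero 'same' padding), 2x2 max/average pooling, 2x2 nearest-neighbour
up-sampling, channel concatenation and slicing.  Data is kept in float32 by
default; gradients accumulate in the dtype of the forward pass.

Gradients are computed by :meth:`Tensor.backward`, which topologically sorts
the recorded graph and applies each node's stored backward closure.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


def _as_array(x, dtype=DEFAULT_DTYPE):
    if isinstance(x, Tensor):
        raise TypeError("expected raw array-like, got Tensor")
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        arr = np.asarray(data)
        if dtype is None:
            dtype = arr.dtype if arr.dtype in (np.float32, np.float64) \
                else DEFAULT_DTYPE
        self.data = np.asarray(arr, dtype=dtype)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.requires_grad = any(p.requires_grad for p in parents)
        out.grad = None
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        else:
            out._parents = ()
            out._backward = None
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (M timesteps)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            if node._parents == () or node._backward is None:
                # leaf: accumulate into .grad
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad += g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(other, dtype=self.data.dtype)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data
        def backward(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))
        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data
        def backward(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))
        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data
        def backward(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.data.shape)))
        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data ** p
        def backward(g):
            return ((self, g * p * self.data ** (p - 1.0)),)
        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return ((self, full),)
        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape
        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, shape).astype(self.data.dtype)),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, shape).astype(self.data.dtype)),)
        return Tensor._make(np.asarray(out_data, dtype=self.data.dtype),
                            (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)
        def backward(g):
            return ((self, g.reshape(old)),)
        return Tensor._make(out_data, (self,), backward)


# -- pointwise nonlinearities -------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)
    return Tensor._make(out_data, (x,), lambda g: ((x, g * mask),))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._make(s, (x,), lambda g: ((x, g * s * (1.0 - s)),))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return Tensor._make(t, (x,), lambda g: ((x, g * (1.0 - t * t)),))


def abs_(x: Tensor) -> Tensor:
    s = np.sign(x.data)
    return Tensor._make(np.abs(x.data), (x,), lambda g: ((x, g * s),))


def sqrt(x: Tensor, eps: float = 0.0) -> Tensor:
    r = np.sqrt(x.data + eps)
    def backward(g):
        return ((x, g * 0.5 / np.maximum(r, 1e-12)),)
    return Tensor._make(r, (x,), backward)


# -- linear algebra -----------------------------------------------------------

def matmul(x: Tensor, w: Tensor) -> Tensor:
    out_data = x.data @ w.data
    def backward(g):
        return ((x, g @ w.data.T), (w, x.data.T @ g))
    return Tensor._make(out_data, (x, w), backward)


# -- 2D convolution (stride 1, zero same-padding) ------------------------------

def _sliding(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # x: (N, C, H, W) -> (N, C, H-kh+1, W-kw+1, kh, kw)
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return v


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 'same' 2D convolution (cross-correlation, CNN convention).

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    """
    kh, kw = w.data.shape[2], w.data.shape[3]
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xpad = np.pad(x.data, ((0, 0), (0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw)))
    win = _sliding(xpad, kh, kw)  # (N, Cin, H, W, kh, kw)
    out_data = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward(g):
        # g: (N, Cout, H, W)
        grads = []
        gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # (Cout,Cin,kh,kw)
        # grad wrt x: full correlation of g with spatially flipped kernels
        gpad = np.pad(g, ((0, 0), (0, 0), (kh - 1 - ph, ph), (kw - 1 - pw, pw)))
        gwin = _sliding(gpad, kh, kw)  # (N, Cout, H, W, kh, kw)
        wflip = w.data[:, :, ::-1, ::-1]
        gx = np.tensordot(gwin, wflip, axes=([1, 4, 5], [0, 2, 3]))  # (N,H,W,Cin)
        gx = np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
        grads.append((x, gx))
        grads.append((w, gw))
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


# -- pooling / resampling ------------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(h, w)}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = xr.max(axis=(3, 5))
    def backward(g):
        mask = xr == out_data[:, :, :, None, :, None]
        # split gradient between tied maxima so it stays well-defined
        cnt = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None] / cnt)
        return ((x, gx.reshape(n, c, h, w)),)
    return Tensor._make(out_data, (x,), backward)


def avgpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {(h, w)}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = xr.mean(axis=(3, 5))
    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        return ((x, gx),)
    return Tensor._make(out_data, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """2x2 nearest-neighbour up-sampling."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    n, c, h, w = x.data.shape
    def backward(g):
        gr = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        return ((x, gr),)
    return Tensor._make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        grads = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            grads.append((t, g[tuple(sl)]))
        return tuple(grads)
    return Tensor._make(out_data, tuple(tensors), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))
    def backward(g):
        gx = np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape)
        return ((x, gx.astype(x.data.dtype)),)
    return Tensor._make(out_data, (x,), backward)
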