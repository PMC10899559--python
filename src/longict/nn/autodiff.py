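"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations needed by the attention model live here: broadcasting
arithmetic, batched matmul, reductions, softmax with additive ``-inf``
masking, a strided 2-D convolution and gather-style indexing.  Everything is
float64; graphs are built eagerly and freed after :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "logsumexp", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
        # free the graph so cached tensors can be reused across steps
        for t in topo:
            t._parents, t._backward = (), None

    def zero_grad(self) -> None:
        self.grad = None

    # -- shape views -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,),
            lambda g, s=self, o=old: s._accum(g.reshape(o)))

    def swapaxes(self, a: int, b: int) -> "Tensor":
        return Tensor._make(
            np.swapaxes(self.data, a, b), (self,),
            lambda g, s=self: s._accum(np.swapaxes(g, a, b)))

    def __getitem__(self, idx) -> "Tensor":
        def back(g, s=self, idx=idx):
            full = np.zeros_like(s.data)
            np.add.at(full, idx, g)
            s._accum(full)
        return Tensor._make(self.data[idx], (self,), back)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        o = _as_tensor(other)
        def back(g, a=self, b=o):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return Tensor._make(self.data + o.data, (self, o), back)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), lambda g, s=self: s._accum(-g))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        o = _as_tensor(other)
        def back(g, a=self, b=o):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return Tensor._make(self.data * o.data, (self, o), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data ** p
        def back(g, s=self, p=p, od=out_data):
            s._accum(g * p * s.data ** (p - 1.0))
        return Tensor._make(out_data, (self,), back)

    def __matmul__(self, other) -> "Tensor":
        o = _as_tensor(other)
        def back(g, a=self, b=o):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))
        return Tensor._make(self.data @ o.data, (self, o), back)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g, s=self, od=out_data: s._accum(g * od))

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,),
                            lambda g, s=self: s._accum(g / s.data))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,),
                            lambda g, s=self, m=mask: s._accum(g * m))

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g, s=self, od=out_data: s._accum(g * (1 - od ** 2)))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def back(g, s=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            s._accum(np.broadcast_to(g, s.data.shape).copy())
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis``; entries equal to ``-inf`` get exactly zero mass."""
    z = x.data - np.max(x.data, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore"):
        e = np.exp(z)
    e = np.nan_to_num(e, nan=0.0)  # fully-masked rows (max = -inf) become 0
    denom = e.sum(axis=axis, keepdims=True)
    denom[denom == 0.0] = 1.0
    y = e / denom

    def back(g, x=x, y=y, axis=axis):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor._make(y, (x,), back)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = np.log(s) + m
    soft = e / s

    def back(g, x=x, soft=soft, axis=axis, keepdims=keepdims):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(g * soft)

    return Tensor._make(out_data if keepdims else np.squeeze(out_data, axis),
                        (x,), back)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation.  ``x``: (N,C,H,W), ``w``: (F,C,kh,kw)."""
    s, p = int(stride), int(padding)
    n, c, h, wd = x.data.shape
    f, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]                      # (N, C, Ho, Wo, kh, kw)
    out_data = np.einsum("nchwkl,fckl->nfhw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    ho, wo = out_data.shape[2:]
    parents = (x, w) if b is None else (x, w, b)

    def back(g):
        if w.requires_grad:
            w._accum(np.einsum("nchwkl,nfhw->fckl", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += np.einsum(
                        "fc,nfhw->nchw", w.data[:, :, i, j], g, optimize=True)
            x._accum(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

    return Tensor._make(out_data, parents, back)
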