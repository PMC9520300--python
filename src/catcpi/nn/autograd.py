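"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation, a
closure that propagates gradients to its parents.  ``backward()`` runs a
topological sort of the recorded graph and accumulates ``grad`` arrays on every
tensor created with ``requires_grad=True``.

The op set is exactly what the interaction model needs: broadcasting
arithmetic, matmul (with stacked batch dimensions), elementwise nonlinearities,
reductions, shape ops, 2D/1D convolution and max-pooling via im2col, and an
embedding gather.  Dtypes follow the inputs, so float64 graphs retain float64
precision while model parameters can live in float32 for speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def as_tensor(x, requires_grad: bool = False) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x), requires_grad=requires_grad)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    # make numpy defer to the reflected operators below
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._grad_owned = False
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        # Adopt the first contribution without a zero-fill pass or copy; the
        # adopted array may alias another tensor's grad, so only accumulate
        # in place once this tensor owns a private buffer.
        if self.grad is None:
            g = np.asarray(g)
            if g.shape != self.data.shape:
                g = np.broadcast_to(g, self.data.shape)
            self.grad = g.astype(self.data.dtype, copy=False)
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    _grad_enabled = True

    @staticmethod
    def _node(data, parents, backward):
        req = Tensor._grad_enabled and any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else (),
                      _backward=backward if req else None)

    def _coerce(self, other) -> "Tensor":
        """Wrap scalars at this tensor's float dtype (avoid silent upcasts)."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0 and arr.dtype.kind == "f" and self.data.dtype.kind == "f":
            arr = arr.astype(self.data.dtype, copy=False)
        return Tensor(arr)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape).astype(self.data.dtype, copy=False))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape).astype(other.data.dtype, copy=False))

        return Tensor._node(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape).astype(self.data.dtype, copy=False))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape).astype(other.data.dtype, copy=False))

        return Tensor._node(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape).astype(self.data.dtype, copy=False))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2,
                                          other.data.shape).astype(other.data.dtype, copy=False))

        return Tensor._node(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._node(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            a, b = self.data, other.data
            aa = a[None, :] if a.ndim == 1 else a
            bb = b[:, None] if b.ndim == 1 else b
            if a.ndim == 1 and b.ndim == 1:
                gg = np.reshape(g, (1, 1))
            elif a.ndim == 1:
                gg = np.expand_dims(g, -2)
            elif b.ndim == 1:
                gg = np.expand_dims(g, -1)
            else:
                gg = g
            if self.requires_grad:
                ga = gg @ np.swapaxes(bb, -1, -2)
                ga = (_unbroadcast(ga, (1,) + a.shape).reshape(a.shape)
                      if a.ndim == 1 else _unbroadcast(ga, a.shape))
                self._accum(ga.astype(a.dtype, copy=False))
            if other.requires_grad:
                gb = np.swapaxes(aa, -1, -2) @ gg
                gb = (_unbroadcast(gb, b.shape + (1,)).reshape(b.shape)
                      if b.ndim == 1 else _unbroadcast(gb, b.shape))
                other._accum(gb.astype(b.dtype, copy=False))

        return Tensor._node(out_data, (self, other), bwd)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._node(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._node(out_data, (self,), bwd)

    def sqrt(self):
        return self**0.5

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (self,), bwd)

    def leaky_relu(self, alpha: float = 0.01):
        """x if x >= 0 else alpha*x."""
        dt = self.data.dtype if self.data.dtype.kind == "f" else np.float64
        # slope factor: 1 where x >= 0, alpha elsewhere (single fast pass)
        fac = (self.data >= 0).astype(dt)
        fac *= (1.0 - alpha)
        fac += alpha
        out_data = self.data * fac

        def bwd(g):
            if self.requires_grad:
                self._accum((g * fac).astype(self.data.dtype, copy=False))

        return Tensor._node(out_data, (self,), bwd)

    def softplus(self):
        """log(1 + e^x), computed stably; gradient is sigmoid(x)."""
        out_data = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor._node(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only inside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(np.where(inside, g, 0.0).astype(self.data.dtype, copy=False))

        return Tensor._node(out_data, (self,), bwd)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                gp = g * out_data
                self._accum((gp - out_data * gp.sum(axis=axis, keepdims=True)).astype(self.data.dtype, copy=False))

        return Tensor._node(out_data, (self,), bwd)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, g if np.isscalar(g) else g.reshape(())))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).astype(self.data.dtype, copy=False))

        return Tensor._node(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(in_shape))

        return Tensor._node(out_data, (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._node(out_data, (self,), bwd)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def bwd(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return Tensor._node(out_data, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._node(out_data, (self,), bwd)

    @staticmethod
    def concat(tensors, axis: int = 0):
        tensors = [as_tensor(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)].astype(t.data.dtype, copy=False))

        return Tensor._node(out_data, tuple(tensors), bwd)

    @staticmethod
    def stack(tensors, axis: int = 0):
        tensors = [as_tensor(t) for t in tensors]
        out_data = np.stack([t.data for t in tensors], axis=axis)

        def bwd(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis).astype(t.data.dtype, copy=False))

        return Tensor._node(out_data, tuple(tensors), bwd)

    # ------------------------------------------------------------ embeddings
    @staticmethod
    def embedding(table: "Tensor", ids: np.ndarray):
        """Gather rows ``table[ids]``; scatter-adds gradients back."""
        ids = np.asarray(ids)
        out_data = table.data[ids]

        def bwd(g):
            if table.requires_grad:
                full = np.zeros_like(table.data)
                np.add.at(full, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
                table._accum(full)

        return Tensor._node(out_data, (table,), bwd)

    # ---------------------------------------------------------- convolutions
    @staticmethod
    def conv2d(x: "Tensor", w: "Tensor", b: "Tensor", pad: int = 1):
        """Stride-1 2D convolution. x:(B,C,H,W), w:(Co,C,kh,kw), b:(Co,)."""
        B, C, H, W = x.data.shape
        Co, Ci, kh, kw = w.data.shape
        if Ci != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        Ho, Wo = H + 2 * pad - kh + 1, W + 2 * pad - kw + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
        wmat = w.data.reshape(Co, -1)
        out = cols @ wmat.T + b.data
        out_data = out.transpose(0, 2, 1).reshape(B, Co, Ho, Wo)

        def bwd(g):
            gmat = g.reshape(B, Co, Ho * Wo).transpose(0, 2, 1)  # (B, P, Co)
            if b.requires_grad:
                b._accum(gmat.sum(axis=(0, 1)).astype(b.data.dtype, copy=False))
            if w.requires_grad:
                gw = gmat.reshape(-1, Co).T @ cols.reshape(-1, C * kh * kw)
                w._accum(gw.reshape(w.data.shape).astype(w.data.dtype, copy=False))
            if x.requires_grad:
                gcols = gmat @ wmat  # (B, P, C*kh*kw)
                gcols = gcols.reshape(B, Ho, Wo, C, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + Ho, j:j + Wo] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                gx = gxp[:, :, pad:pad + H, pad:pad + W] if pad else gxp
                x._accum(gx.astype(x.data.dtype, copy=False))

        return Tensor._node(out_data, (x, w, b), bwd)

    @staticmethod
    def conv1d(x: "Tensor", w: "Tensor", b: "Tensor", pad: int = 1):
        """Stride-1 1D convolution. x:(B,C,L), w:(Co,C,k), b:(Co,)."""
        B, C, L = x.data.shape
        Co, Ci, k = w.data.shape
        if Ci != C:
            raise ValueError(f"conv1d channel mismatch: input {C}, weight {Ci}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
        Lo = L + 2 * pad - k + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,Lo,k)
        cols = win.transpose(0, 2, 1, 3).reshape(B, Lo, C * k)
        wmat = w.data.reshape(Co, -1)
        out = cols @ wmat.T + b.data
        out_data = out.transpose(0, 2, 1)

        def bwd(g):
            gmat = g.transpose(0, 2, 1)  # (B, Lo, Co)
            if b.requires_grad:
                b._accum(gmat.sum(axis=(0, 1)).astype(b.data.dtype, copy=False))
            if w.requires_grad:
                gw = gmat.reshape(-1, Co).T @ cols.reshape(-1, C * k)
                w._accum(gw.reshape(w.data.shape).astype(w.data.dtype, copy=False))
            if x.requires_grad:
                gcols = (gmat @ wmat).reshape(B, Lo, C, k)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    gxp[:, :, i:i + Lo] += gcols[:, :, :, i].transpose(0, 2, 1)
                gx = gxp[:, :, pad:pad + L] if pad else gxp
                x._accum(gx.astype(x.data.dtype, copy=False))

        return Tensor._node(out_data, (x, w, b), bwd)

    @staticmethod
    def maxpool2d(x: "Tensor", size: int = 2):
        B, C, H, W = x.data.shape
        if H % size or W % size:
            raise ValueError(f"maxpool2d: spatial dims ({H},{W}) not divisible by {size}")
        Ho, Wo = H // size, W // size
        xr = x.data.reshape(B, C, Ho, size, Wo, size)
        out_data = xr.max(axis=(3, 5))

        def bwd(g):
            if not x.requires_grad:
                return
            # winner-take-first: route gradient to the first argmax per window
            win = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 3, 5)
                                       ).reshape(B, C, Ho, Wo, size * size)
            idx = win.argmax(axis=-1)
            gr = np.zeros((B, C, Ho, Wo, size * size), dtype=x.data.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(B, C, Ho, Wo, size, size).transpose(0, 1, 2, 4, 3, 5)
            x._accum(gr.reshape(B, C, H, W))

        return Tensor._node(out_data, (x,), bwd)

    @staticmethod
    def maxpool1d(x: "Tensor", size: int = 2):
        B, C, L = x.data.shape
        if L % size:
            raise ValueError(f"maxpool1d: length {L} not divisible by {size}")
        Lo = L // size
        xr = x.data.reshape(B, C, Lo, size)
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            if not x.requires_grad:
                return
            gr = np.zeros((B, C, Lo, size), dtype=x.data.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            x._accum(gr.reshape(B, C, L))

        return Tensor._node(out_data, (x,), bwd)


class no_grad:
    """Context manager: ops inside build no graph (inference mode)."""

    def __enter__(self):
        self._prev = Tensor._grad_enabled
        Tensor._grad_enabled = False

    def __exit__(self, *exc):
        Tensor._grad_enabled = self._prev
        return False
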