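"""Layer abstractions over the autograd engine.

Modules hold named :class:`Tensor` parameters (and non-trainable buffers such
as batch-norm running statistics) and expose ``parameters()`` /
``state_dict()`` by dotted path for the optimizer and checkpointing.
Initialization is driven by an explicit ``numpy.random.Generator`` so a model
is a pure function of its config and seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

DTYPE = np.float32


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name.startswith("buffer:"):
                bname = name[len("buffer:"):]
                *path, leaf = bname.split(".")
                mod = self
                for p in path:
                    mod = mod._modules[p]
                mod._buffers[leaf][...] = arr
            else:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch loading {name}")
                params[name].data[...] = arr

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    scale = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * scale).astype(DTYPE)


def _norm_op(x: Tensor, gamma: Tensor, beta: Tensor, axes, shape, eps: float,
             mean: np.ndarray | None = None, var: np.ndarray | None = None,
             param_axes=None) -> Tensor:
    """Fused normalization: (x - mean)/sqrt(var+eps) * gamma + beta.

    ``axes`` are the statistic axes; ``param_axes`` (default: same) are the
    axes summed over for the gamma/beta gradients.  With ``mean``/``var``
    given (running statistics, eval mode) they are treated as constants;
    otherwise batch statistics are used and the backward pass applies the
    full batch-norm gradient.
    """
    param_axes = axes if param_axes is None else param_axes
    xd = x.data
    batch_stats = mean is None
    if batch_stats:
        mean = xd.mean(axis=axes, keepdims=True)
        var = xd.var(axis=axes, keepdims=True)
    else:
        mean = mean.reshape(shape)
        var = var.reshape(shape)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean) * ivar
    gam = gamma.data.reshape(shape)
    out = xhat * gam + beta.data.reshape(shape)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=param_axes).reshape(gamma.data.shape)
                         .astype(gamma.data.dtype, copy=False))
        if beta.requires_grad:
            beta._accum(g.sum(axis=param_axes).reshape(beta.data.shape)
                        .astype(beta.data.dtype, copy=False))
        if x.requires_grad:
            if batch_stats:
                gmean = g.mean(axis=axes, keepdims=True)
                gx_mean = (g * xhat).mean(axis=axes, keepdims=True)
                x._accum(((g - gmean - xhat * gx_mean) * (gam * ivar)).astype(xd.dtype, copy=False))
            else:
                x._accum((g * (gam * ivar)).astype(xd.dtype, copy=False))

    out_t = Tensor._node(out, (x, gamma, beta), bwd)
    return out_t, (mean, var) if batch_stats else (None, None)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(_kaiming(rng, (d_in, d_out), d_in), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, pad: int | None = None):
        super().__init__()
        self.pad = k // 2 if pad is None else pad
        self.w = Tensor(_kaiming(rng, (c_out, c_in, k, k), c_in * k * k), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return Tensor.conv2d(x, self.w, self.b, pad=self.pad)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, pad: int | None = None):
        super().__init__()
        self.pad = k // 2 if pad is None else pad
        self.w = Tensor(_kaiming(rng, (c_out, c_in, k), c_in * k), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return Tensor.conv1d(x, self.w, self.b, pad=self.pad)


class _BatchNorm(Module):
    """Per-channel batch normalization; running stats used in eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(channels, dtype=DTYPE))

    def _norm(self, x: Tensor, axes: tuple, shape: tuple) -> Tensor:
        if self.training:
            out, (mean, var) = _norm_op(x, self.gamma, self.beta, axes, shape, self.eps)
            self.running_mean += self.momentum * (mean.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.reshape(-1) - self.running_var)
            return out
        out, _ = _norm_op(x, self.gamma, self.beta, axes, shape, self.eps,
                          mean=self.running_mean, var=self.running_var)
        return out


class BatchNorm2d(_BatchNorm):
    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1)
        return self._norm(x, (0, 2, 3), shape)


class BatchNorm1d(_BatchNorm):
    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1)
        return self._norm(x, (0, 2), shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1,) * (x.ndim - 1) + (-1,)
        out, _ = _norm_op(x, self.gamma, self.beta, -1, shape, self.eps,
                          param_axes=tuple(range(x.ndim - 1)))
        return out


class Embedding(Module):
    """Token-id lookup table; row 0 is the pad embedding, initialized to zero."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator, zero_pad_row: bool = True):
        super().__init__()
        init = (rng.standard_normal((n_tokens, dim)) * 0.02).astype(DTYPE)
        if zero_pad_row:
            init[0] = 0.0
        self.table = Tensor(init, requires_grad=True)

    def forward(self, ids: np.ndarray) -> Tensor:
        if np.max(ids, initial=0) >= self.table.data.shape[0]:
            raise IndexError("token id out of embedding-table range")
        return Tensor.embedding(self.table, ids)
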