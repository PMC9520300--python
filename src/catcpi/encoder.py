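"""Shared representation machinery for both branches.

The image path is CNN block -> channels-as-tokens flattening -> sinusoidal
position embedding -> transformer encoder; the protein path reuses the same
encoder architecture (separate weights) on embedded k-gram tokens.

Channels-as-tokens: the CNN output W0 in R^{C x H x W} is flattened row-major
per channel to W1 in R^{N x D} with N = C and D = H*W — each channel's
spatial map becomes one transformer token.

Attention follows scaled dot-product form: softmax(Q K^T / sqrt(Dh)) V with
Dh = D / heads, so compute and parameter count stay constant as the head
count varies.  Encoder layers are pre-norm with stochastic depth (DropPath)
on both residual branches:

    z <- z + DropPath(MSA(LN(z)));  z <- z + DropPath(MLP(LN(z)))
"""

from __future__ import annotations

import numpy as np

from .config import CnnBlockConfig, EncoderConfig
from .mol_image import MoleculeImage
from .nn import (DTYPE, BatchNorm2d, Conv2d, LayerNorm, Linear, Module, Tensor,
                 as_tensor)


def positional_encoding(n: int, d: int) -> np.ndarray:
    """Fixed sinusoidal position embedding.

    PE(pos, 2i) = sin(pos / 10000^(2i/D)), PE(pos, 2i+1) = cos(pos / 10000^(2i/D)).
    """
    if d % 2:
        raise ValueError(f"embedding dimension must be even, got {d}")
    pos = np.arange(n)[:, None].astype(np.float64)
    i = np.arange(d // 2)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, 2.0 * i / d)
    pe = np.empty((n, d), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def self_attention(q, k, v) -> Tensor:
    """softmax(Q K^T / sqrt(Dh)) V over the key axis; shapes (..., N, Dh)."""
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if q.shape != k.shape or k.shape[:-1] != v.shape[:-1]:
        raise ValueError(f"inconsistent attention shapes {q.shape}/{k.shape}/{v.shape}")
    dh = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
    return scores.softmax(axis=-1) @ v


def attention_probabilities(q, k) -> np.ndarray:
    """The softmax attention matrix alone (rows sum to 1); diagnostic."""
    q, k = as_tensor(q), as_tensor(k)
    dh = q.shape[-1]
    return ((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))).softmax(axis=-1).data


def multi_head_attention(z, heads: int, projections: dict) -> Tensor:
    """MSA(z) = [SA_1(z); ...; SA_k(z)] U_msa with per-head width Dh = D/heads.

    ``projections`` maps 'wq'/'wk'/'wv'/'u_msa' to (D, D) matrices; columns of
    the q/k/v projections are split contiguously across heads.
    """
    z = as_tensor(z)
    d = z.shape[-1]
    if d % heads:
        raise ValueError(f"token dim {d} not divisible by heads {heads}")
    dh = d // heads
    q = z @ as_tensor(projections["wq"])
    k = z @ as_tensor(projections["wk"])
    v = z @ as_tensor(projections["wv"])
    outs = []
    for h in range(heads):
        sl = slice(h * dh, (h + 1) * dh)
        outs.append(self_attention(q[..., sl], k[..., sl], v[..., sl]))
    return Tensor.concat(outs, axis=-1) @ as_tensor(projections["u_msa"])


class MultiHeadAttention(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.token_dim
        self.heads = cfg.heads
        self.dh = cfg.head_dim
        scale = 1.0 / np.sqrt(d)
        for name in ("wq", "wk", "wv", "u_msa"):
            setattr(self, name, Tensor((rng.standard_normal((d, d)) * scale).astype(DTYPE),
                                       requires_grad=True))

    def forward(self, z: Tensor) -> Tensor:
        # fused equivalent of per-head slicing: reshape to (..., heads, N, Dh)
        d = z.shape[-1]
        lead = z.shape[:-2]
        n = z.shape[-2]
        q = (z @ self.wq).reshape(*lead, n, self.heads, self.dh).swapaxes(-2, -3)
        k = (z @ self.wk).reshape(*lead, n, self.heads, self.dh).swapaxes(-2, -3)
        v = (z @ self.wv).reshape(*lead, n, self.heads, self.dh).swapaxes(-2, -3)
        sa = self_attention(q, k, v)
        out = sa.swapaxes(-2, -3).reshape(*lead, n, d)
        return out @ self.u_msa


class Mlp(Module):
    def __init__(self, d: int, ratio: int, rng: np.random.Generator, slope: float = 0.01):
        super().__init__()
        self.slope = slope
        self.fc1 = Linear(d, ratio * d, rng)
        self.fc2 = Linear(ratio * d, d, rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.fc2(self.fc1(z).leaky_relu(self.slope))


class EncoderLayer(Module):
    """Pre-norm transformer layer with DropPath on both residual branches."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.rate = cfg.droppath_rate
        self.ln1 = LayerNorm(cfg.token_dim)
        self.msa = MultiHeadAttention(cfg, rng)
        self.ln2 = LayerNorm(cfg.token_dim)
        self.mlp = Mlp(cfg.token_dim, cfg.mlp_ratio, rng)
        self._rng = rng

    def _droppath(self, branch: Tensor, batched: bool) -> Tensor:
        if not self.training or self.rate == 0.0:
            return branch
        if self.rate >= 1.0:
            return branch * 0.0
        keep = 1.0 - self.rate
        shape = (branch.shape[0], 1, 1) if batched else (1, 1)
        mask = (self._rng.random(shape) < keep).astype(branch.dtype) / keep
        return branch * mask

    def forward(self, z: Tensor) -> Tensor:
        batched = z.ndim == 3
        z = z + self._droppath(self.msa(self.ln1(z)), batched)
        z = z + self._droppath(self.mlp(self.ln2(z)), batched)
        return z


class TransformerEncoder(Module):
    """Position embedding followed by ``depth`` encoder layers."""

    def __init__(self, n_tokens: int, cfg: EncoderConfig, rng: np.random.Generator,
                 add_pe: bool = True):
        super().__init__()
        self.cfg = cfg
        self.add_pe = add_pe
        self.register_buffer("pe", positional_encoding(n_tokens, cfg.token_dim))
        for i in range(cfg.depth):
            setattr(self, f"layer{i}", EncoderLayer(cfg, rng))
        self.depth = cfg.depth

    def forward(self, z: Tensor) -> Tensor:
        if self.add_pe:
            z = z + Tensor(self.pe.astype(z.data.dtype, copy=False))
        for i in range(self.depth):
            z = getattr(self, f"layer{i}")(z)
        return z


class CnnBlock(Module):
    """Stacked Conv -> BatchNorm -> LeakyReLU -> (MaxPool) stages."""

    def __init__(self, cfg: CnnBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        for i, (cin, cout, k, stride, pad, pool) in enumerate(cfg.stages):
            if stride != 1:
                raise ValueError("only stride-1 convolutions are supported")
            setattr(self, f"conv{i}", Conv2d(cin, cout, k, rng, pad=pad))
            setattr(self, f"bn{i}", BatchNorm2d(cout))
        self.n_stages = len(cfg.stages)

    def forward(self, x: Tensor) -> Tensor:
        a = self.cfg.activation_slope
        for i, (_, _, _, _, _, pool) in enumerate(self.cfg.stages):
            x = getattr(self, f"bn{i}")(getattr(self, f"conv{i}")(x)).leaky_relu(a)
            if pool > 1:
                x = Tensor.maxpool2d(x, pool)
        return x


def cnn_block(img: MoleculeImage | np.ndarray, block: CnnBlock) -> Tensor:
    """Run the CNN block on a single image; returns the (C, H, W) map."""
    px = img.pixels if isinstance(img, MoleculeImage) else np.asarray(img)
    expect = block.cfg.stages[0][0]
    if px.ndim != 3 or px.shape[0] != expect:
        raise ValueError(f"expected ({expect},S,S) input, got {px.shape}")
    out = block(Tensor(px[None].astype(np.float64)))
    return out.reshape(out.shape[1:])


def flatten_tokens(w0) -> Tensor:
    """Channels-as-tokens: (..., C, H, W) -> (..., N=C, D=H*W), row-major."""
    w0 = as_tensor(w0)
    *lead, c, h, w = w0.shape
    return w0.reshape(*lead, c, h * w)


def unflatten_tokens(w1, h: int, w: int) -> Tensor:
    w1 = as_tensor(w1)
    *lead, c, d = w1.shape
    if d != h * w:
        raise ValueError("dimension mismatch in unflatten")
    return w1.reshape(*lead, c, h, w)


def encode(tokens, n_tokens: int, cfg: EncoderConfig, seed: int = 0,
           training: bool = False, add_pe: bool = True) -> Tensor:
    """Functional wrapper: fresh seeded encoder applied to a token map."""
    enc = TransformerEncoder(n_tokens, cfg, np.random.default_rng(seed), add_pe=add_pe)
    enc.train(training)
    return enc(as_tensor(tokens))
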