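"""End-to-end networks for CPI and DDI prediction, plus ablation variants.

CPI: render -> CNN block -> channels-as-tokens -> +PE -> transformer (compound
branch); k-gram ids -> embedding -> +PE -> transformer (protein branch,
separate weights, same architecture); stack -> Feature Relearning -> sigmoid.

DDI: both SMILES pass through the SAME compound branch (shared weights); the
two maps are stacked and fused by FR.

Ablation variants:
  no_cnn     image cut into non-overlapping patches (patch count = N), each
             flattened and linearly mapped to D, fed straight to the encoder
  no_trans   compound transformer removed; CNN block deepened by two extra
             conv stages, output reshaped to N x D
  no_p_trans protein transformer removed; embeddings (+PE) go to fusion
  no_fr      both maps flattened and concatenated into a single fully
             connected sigmoid head (no FR stages)
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .encoder import (CnnBlock, TransformerEncoder, flatten_tokens,
                      positional_encoding)
from .fusion import FeatureRelearning, stack_maps
from .nn import DTYPE, BatchNorm2d, Conv2d, Embedding, Linear, Module, Tensor


class _PatchEmbed(Module):
    """Non-overlapping patch tokenizer used by the no_cnn variant."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        grid = int(round(np.sqrt(cfg.n_tokens)))
        if grid * grid != cfg.n_tokens:
            raise ValueError("no_cnn variant needs a square token count")
        if cfg.image_size % grid:
            raise ValueError("image size must be divisible by the patch grid")
        self.grid = grid
        self.patch = cfg.image_size // grid
        self.proj = Linear(3 * self.patch**2, cfg.token_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c, s, _ = x.shape
        g, p = self.grid, self.patch
        x = x.reshape(b, c, g, p, g, p).transpose((0, 2, 4, 1, 3, 5))
        x = x.reshape(b, g * g, c * p * p)
        return self.proj(x)


class _DeepCnnTail(Module):
    """Two extra conv stages replacing the compound transformer (no_trans)."""

    def __init__(self, channels: int, slope: float, rng: np.random.Generator):
        super().__init__()
        self.slope = slope
        self.conv_a = Conv2d(channels, channels, 3, rng, pad=1)
        self.bn_a = BatchNorm2d(channels)
        self.conv_b = Conv2d(channels, channels, 3, rng, pad=1)
        self.bn_b = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn_a(self.conv_a(x)).leaky_relu(self.slope)
        return self.bn_b(self.conv_b(x)).leaky_relu(self.slope)


class InteractionNet(Module):
    """The complete model; ``task`` and ``variant`` come from the config."""

    def __init__(self, config: ModelConfig, vocab_size: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.config = config
        n, d = config.n_tokens, config.token_dim
        enc_cfg = config.encoder_config()

        # compound branch
        if config.variant == "no_cnn":
            self.patches = _PatchEmbed(config, rng)
        else:
            self.cnn = CnnBlock(config.cnn_config(), rng)
            if config.variant == "no_trans":
                self.cnn_tail = _DeepCnnTail(config.cnn_config().out_channels,
                                             config.leaky_slope, rng)
        if config.variant not in ("no_trans",):
            self.comp_encoder = TransformerEncoder(n, enc_cfg, rng)

        # protein branch (CPI only)
        if config.task == "cpi":
            if vocab_size is None:
                raise ValueError("CPI model requires the k-gram vocabulary size")
            self.vocab_size = vocab_size
            self.embedding = Embedding(vocab_size, d, rng)
            if config.variant != "no_p_trans":
                self.prot_encoder = TransformerEncoder(n, enc_cfg, rng)
            else:
                self.register_buffer("prot_pe", positional_encoding(n, d).astype(DTYPE))

        # fusion head
        if config.variant == "no_fr":
            self.head = Linear(2 * n * d, 1, rng)
        else:
            self.fr = FeatureRelearning(config, rng)

    # ------------------------------------------------------------- branches
    def compound_features(self, images: np.ndarray | Tensor) -> Tensor:
        """(B, 3, S, S) images -> (B, N, D) compound feature map."""
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=DTYPE))
        if self.config.variant == "no_cnn":
            tokens = self.patches(x)
        else:
            w0 = self.cnn(x)
            if self.config.variant == "no_trans":
                return flatten_tokens(self.cnn_tail(w0))
            tokens = flatten_tokens(w0)
        return self.comp_encoder(tokens)

    def protein_features(self, prot_ids: np.ndarray) -> Tensor:
        """(B, N) k-gram ids -> (B, N, D) protein feature map."""
        emb = self.embedding(np.asarray(prot_ids))
        if self.config.variant == "no_p_trans":
            return emb + Tensor(self.prot_pe)
        return self.prot_encoder(emb)

    # -------------------------------------------------------------- forward
    def _fuse_logit(self, first: Tensor, second: Tensor) -> Tensor:
        if self.config.variant == "no_fr":
            b, n, d = first.shape
            flat = Tensor.concat([first.reshape(b, n * d), second.reshape(b, n * d)], axis=-1)
            return self.head(flat).reshape(b)
        return self.fr.forward_logit(stack_maps(first, second))

    def forward_logits(self, images, second) -> Tensor:
        xc = self.compound_features(images)
        if self.config.task == "cpi":
            xp = self.protein_features(second)
        else:
            xp = self.compound_features(second)  # shared weights by construction
        return self._fuse_logit(xc, xp)

    def forward(self, images, second) -> Tensor:
        """CPI: (images, protein ids); DDI: (images_a, images_b) -> (B,) probs."""
        return self.forward_logits(images, second).sigmoid()


def make_variant(config: ModelConfig, variant: str, vocab_size: int | None = None,
                 rng: np.random.Generator | None = None) -> InteractionNet:
    """Build an ablation variant of the configured model."""
    import dataclasses

    cfg = dataclasses.replace(config, variant=variant)  # validates the name
    return InteractionNet(cfg, vocab_size=vocab_size, rng=rng)


def count_parameters(net: Module, prefix: str = "") -> int:
    return sum(p.data.size for name, p in net.named_parameters()
               if name.startswith(prefix))
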