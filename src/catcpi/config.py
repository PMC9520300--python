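"""Architecture and training hyperparameter containers.

All defaults of the published architecture live here: molecular images of
128x128 pixels, k=3 protein k-grams, N=64 tokens of dimension D=256, a
pre-norm transformer encoder (depth 4, 8 heads, MLP ratio 4, DropPath 0.1),
Adam with learning rate 0.001 and batch size 128.  Every field serializes with
checkpoints and result files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

VARIANTS = ("full", "no_cnn", "no_trans", "no_p_trans", "no_fr")
TASKS = ("cpi", "ddi")


@dataclass(frozen=True)
class CnnBlockConfig:
    """Stage plan for the image CNN block.

    Each stage is Conv(k, stride 1, same pad) -> BatchNorm -> LeakyReLU and,
    when ``pool > 1``, a MaxPool of that size.  The default plan maps a
    3 x S x S image to 64 channels over a ``target_spatial``-sized grid, so
    the flattened token map is N=64 tokens of dimension D=target_spatial^2.
    """

    stages: tuple = ()  # (c_in, c_out, kernel, stride, pad, pool)
    activation_slope: float = 0.01

    @classmethod
    def default(cls, image_size: int = 128, target_spatial: int = 16) -> "CnnBlockConfig":
        if image_size % target_spatial:
            raise ValueError(f"image size {image_size} not divisible by target {target_spatial}")
        n_pools = int(math.log2(image_size // target_spatial))
        if 2 ** n_pools * target_spatial != image_size:
            raise ValueError("image_size / target_spatial must be a power of two")
        channels = [3, 16, 32, 64, 64]
        stages = []
        for i, (cin, cout) in enumerate(zip(channels[:-1], channels[1:])):
            pool = 2 if i < n_pools else 1
            stages.append((cin, cout, 3, 1, 1, pool))
        # more pools than stages (large images): stack extra pools on the tail
        extra = n_pools - len(stages)
        for _ in range(max(extra, 0)):
            stages.append((64, 64, 3, 1, 1, 2))
        return cls(stages=tuple(stages))

    @property
    def out_channels(self) -> int:
        return self.stages[-1][1]

    def out_spatial(self, image_size: int) -> int:
        s = image_size
        for (_, _, _, _, _, pool) in self.stages:
            if s % pool:
                raise ValueError(f"spatial size {s} not divisible by pool {pool}")
            s //= pool
        return s


@dataclass(frozen=True)
class EncoderConfig:
    depth: int = 4
    heads: int = 8
    token_dim: int = 256
    mlp_ratio: int = 4
    droppath_rate: float = 0.1

    def __post_init__(self):
        if self.token_dim % self.heads:
            raise ValueError(f"token_dim {self.token_dim} not divisible by heads {self.heads}")
        if not (0.0 <= self.droppath_rate < 1.0):
            raise ValueError("droppath_rate must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.token_dim // self.heads


@dataclass
class ModelConfig:
    image_size: int = 128
    k: int = 3                      # protein k-gram window
    n_tokens: int = 64              # N: CNN channels == protein token count
    cnn_target_spatial: int = 16    # final CNN grid; D = target^2
    depth: int = 4
    heads: int = 8
    mlp_ratio: int = 4
    droppath_rate: float = 0.1
    fr_conv2d_channels: int = 16
    fr_conv1d_channels: int = 32
    fr_hidden: int = 512
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 30
    seed: int = 0
    task: str = "cpi"
    variant: str = "full"
    protein_subsample: str = "even"  # or "truncate"
    leaky_slope: float = 0.01

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.k < 1 or self.k > 4:
            raise ValueError("k-gram window must be in 1..4")

    @property
    def token_dim(self) -> int:
        return self.cnn_target_spatial ** 2

    def cnn_config(self) -> CnnBlockConfig:
        return CnnBlockConfig.default(self.image_size, self.cnn_target_spatial)

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(depth=self.depth, heads=self.heads, token_dim=self.token_dim,
                             mlp_ratio=self.mlp_ratio, droppath_rate=self.droppath_rate)

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """Small CPU-scale configuration: 64x64 images, depth-2 encoder with 4
        heads, D=64 tokens. Used throughout the tests and worked examples."""
        base = dict(image_size=64, cnn_target_spatial=8, depth=2, heads=4,
                    droppath_rate=0.0, fr_hidden=256, batch_size=32, epochs=30)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls.from_dict(json.loads(s))
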