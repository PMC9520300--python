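"""Feature Relearning (FR): stack-and-convolve fusion of two feature maps.

The compound map Xc and protein (or second-drug) map Xp, each N x D, are
stacked along a new channel axis into a 2 x N x D tensor — position (i, j)
holds the i-th compound token's j-th feature in channel 0 and the i-th
protein token's j-th feature in channel 1 — so a 2D convolution sums
compound and protein contributions at aligned positions, relearning
interaction features instead of compressing both maps to vectors.

Pipeline: Conv2D stage (2->16 ch, 3x3, BN, LeakyReLU, MaxPool 2x2)
       -> reshape (post-pool channels become 1D channels, flattened spatial
          positions the length)
       -> Conv1D stage (16->32, kernel 3, BN, LeakyReLU, MaxPool 2)
       -> flatten -> MLP (one hidden layer) -> linear -> sigmoid probability.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .nn import (BatchNorm1d, BatchNorm2d, Conv1d, Conv2d, Linear, Module,
                 Tensor, as_tensor)


def stack_maps(first, second) -> Tensor:
    """Channel-stack two N x D maps (or batches) into (..., 2, N, D)."""
    first, second = as_tensor(first), as_tensor(second)
    if first.shape != second.shape:
        raise ValueError(f"cannot stack maps of shapes {first.shape} and {second.shape}")
    return Tensor.stack([first, second], axis=-3)


class FeatureRelearning(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        n, d = cfg.n_tokens, cfg.token_dim
        c2, c1 = cfg.fr_conv2d_channels, cfg.fr_conv1d_channels
        self.slope = cfg.leaky_slope
        self.conv2 = Conv2d(2, c2, 3, rng, pad=1)
        self.bn2 = BatchNorm2d(c2)
        self.conv1 = Conv1d(c2, c1, 3, rng, pad=1)
        self.bn1 = BatchNorm1d(c1)
        length = (n // 2) * (d // 2)          # post-pool spatial, flattened
        flat = c1 * (length // 2)             # after 1D pool
        self.fc1 = Linear(flat, cfg.fr_hidden, rng)
        self.fc2 = Linear(cfg.fr_hidden, 1, rng)
        self.fc2.w.data[...] = 0.0  # zero-init classifier: p=0.5 at start

    def forward(self, x: Tensor) -> Tensor:
        """(B, 2, N, D) stacked maps -> (B,) interaction probabilities."""
        return self.forward_logit(x).sigmoid()

    def forward_logit(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        b = x.shape[0]
        h = self.bn2(self.conv2(x)).leaky_relu(self.slope)
        h = Tensor.maxpool2d(h, 2)
        c = h.shape[1]
        h = h.reshape(b, c, h.shape[2] * h.shape[3])
        h = self.bn1(self.conv1(h)).leaky_relu(self.slope)
        h = Tensor.maxpool1d(h, 2)
        h = h.reshape(b, h.shape[1] * h.shape[2])
        h = self.fc1(h).leaky_relu(self.slope)
        return self.fc2(h).reshape(b)


def fr_forward(x, fr: FeatureRelearning, training: bool = False) -> Tensor:
    """Run the FR head on one stacked map (2, N, D) -> scalar probability."""
    fr.train(training)
    p = fr(as_tensor(x))
    if not np.all(np.isfinite(p.data)):
        raise FloatingPointError("non-finite value in FR forward pass")
    return p.reshape(()) if p.data.size == 1 else p
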