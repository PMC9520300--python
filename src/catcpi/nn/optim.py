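"""Adam optimizer (Kingma & Ba) with conventional moment defaults."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        step = self.lr * np.sqrt(bc2) / bc1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = np.asarray(p.grad, dtype=m.dtype)
            # in-place moment updates (single temporary per parameter)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            denom = np.sqrt(v)
            denom += self.eps * np.sqrt(bc2)
            p.data -= (step * m / denom).astype(p.data.dtype, copy=False)
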