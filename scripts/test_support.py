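"""Independent oracles used by the acceptance script (brute-force attention
and direct evaluation of the positional-encoding closed form)."""

import math

import numpy as np


def pe_oracle(n: int, d: int) -> np.ndarray:
    pe = np.zeros((n, d))
    for pos in range(n):
        for i in range(d // 2):
            angle = pos / (10000 ** (2 * i / d))
            pe[pos, 2 * i] = math.sin(angle)
            pe[pos, 2 * i + 1] = math.cos(angle)
    return pe


def attention_oracle(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    n, dh = q.shape
    out = np.zeros_like(v)
    for i in range(n):
        scores = np.array([q[i] @ k[j] / math.sqrt(dh) for j in range(n)])
        scores -= scores.max()
        p = np.exp(scores) / np.exp(scores).sum()
        for j in range(n):
            out[i] += p[j] * v[j]
    return out


def msa_oracle(z: np.ndarray, heads: int, proj: dict) -> np.ndarray:
    d = z.shape[1]
    dh = d // heads
    q, k, v = z @ proj["wq"], z @ proj["wk"], z @ proj["wv"]
    parts = [attention_oracle(q[:, h * dh:(h + 1) * dh], k[:, h * dh:(h + 1) * dh],
                              v[:, h * dh:(h + 1) * dh]) for h in range(heads)]
    return np.concatenate(parts, axis=1) @ proj["u_msa"]
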