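"""Encoder-core contracts: CNN block shapes, channels-as-tokens flattening,
sinusoidal position embedding, scaled-dot-product attention (vs brute-force
oracles), and the pre-norm encoder layer."""

import math

import numpy as np
import pytest

from catcpi.config import CnnBlockConfig, EncoderConfig
from catcpi.encoder import (CnnBlock, EncoderLayer, TransformerEncoder,
                            attention_probabilities, cnn_block, encode,
                            flatten_tokens, multi_head_attention,
                            positional_encoding, self_attention,
                            unflatten_tokens)
from catcpi.mol_image import MoleculeImage
from catcpi.nn import Tensor


# --------------------------------------------------------------- oracles

def pe_oracle(n, d):
    """Direct elementwise evaluation of the printed closed form."""
    pe = np.zeros((n, d))
    for pos in range(n):
        for i in range(d // 2):
            angle = pos / (10000 ** (2 * i / d))
            pe[pos, 2 * i] = math.sin(angle)
            pe[pos, 2 * i + 1] = math.cos(angle)
    return pe


def attention_oracle(q, k, v):
    """O(N^2 * Dh) double loop over positions."""
    n, dh = q.shape
    out = np.zeros_like(v)
    for i in range(n):
        scores = np.array([q[i] @ k[j] / math.sqrt(dh) for j in range(n)])
        scores -= scores.max()
        p = np.exp(scores) / np.exp(scores).sum()
        for j in range(n):
            out[i] += p[j] * v[j]
    return out


def msa_oracle(z, heads, proj):
    """Slice projections per head, run each head separately, concatenate."""
    d = z.shape[1]
    dh = d // heads
    q, k, v = z @ proj["wq"], z @ proj["wk"], z @ proj["wv"]
    parts = [attention_oracle(q[:, h * dh:(h + 1) * dh], k[:, h * dh:(h + 1) * dh],
                              v[:, h * dh:(h + 1) * dh]) for h in range(heads)]
    return np.concatenate(parts, axis=1) @ proj["u_msa"]


# ------------------------------------------------------------ position emb

def test_positional_encoding_at_position_zero():
    pe = positional_encoding(8, 16)
    assert np.all(pe[0, 0::2] == 0.0)
    assert np.all(pe[0, 1::2] == 1.0)


def test_positional_encoding_closed_form_values():
    pe = positional_encoding(4, 4)
    assert pe[1, 0] == pytest.approx(math.sin(1), abs=1e-15)
    assert pe[1, 1] == pytest.approx(math.cos(1), abs=1e-15)
    assert pe[1, 2] == pytest.approx(math.sin(10000 ** (-1 / 2)), abs=1e-15)
    assert pe[1, 3] == pytest.approx(math.cos(10000 ** (-1 / 2)), abs=1e-15)


@pytest.mark.parametrize("n,d", [(8, 16), (64, 256)])
def test_positional_encoding_matches_oracle(n, d):
    np.testing.assert_allclose(positional_encoding(n, d), pe_oracle(n, d), atol=1e-12)
    assert np.all(np.abs(positional_encoding(n, d)) <= 1.0)


def test_positional_encoding_rejects_odd_dim():
    with pytest.raises(ValueError):
        positional_encoding(4, 5)


# ---------------------------------------------------------------- attention

def test_single_token_attention_returns_value(rng):
    q, k, v = (rng.standard_normal((1, 8)) for _ in range(3))
    np.testing.assert_allclose(self_attention(q, k, v).data, v, atol=1e-12)


def test_zero_query_gives_uniform_attention(rng):
    k, v = rng.standard_normal((6, 4)), rng.standard_normal((6, 4))
    out = self_attention(np.zeros((6, 4)), k, v).data
    np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (6, 1)), atol=1e-12)


def test_attention_matches_bruteforce(rng):
    q, k, v = (rng.standard_normal((5, 8)) for _ in range(3))
    np.testing.assert_allclose(self_attention(q, k, v).data,
                               attention_oracle(q, k, v), atol=1e-6)


def test_attention_rows_are_probabilities(rng):
    q, k = rng.standard_normal((9, 6)), rng.standard_normal((9, 6))
    p = attention_probabilities(q, k)
    np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
    assert np.all(p >= 0)


def test_attention_output_in_value_convex_hull(rng):
    q, k, v = (rng.standard_normal((7, 5)) for _ in range(3))
    out = self_attention(q, k, v).data
    assert np.all(out <= v.max(axis=0) + 1e-9)
    assert np.all(out >= v.min(axis=0) - 1e-9)


def test_attention_shape_validation(rng):
    with pytest.raises(ValueError):
        self_attention(rng.standard_normal((4, 3)), rng.standard_normal((5, 3)),
                       rng.standard_normal((5, 3)))


@pytest.mark.parametrize("heads", [1, 2, 4, 8])
def test_multi_head_matches_per_head_loop(rng, heads):
    d = 32
    z = rng.standard_normal((8, d))
    proj = {k: rng.standard_normal((d, d)) for k in ("wq", "wk", "wv", "u_msa")}
    np.testing.assert_allclose(multi_head_attention(z, heads, proj).data,
                               msa_oracle(z, heads, proj), atol=1e-6)


def test_single_head_identity_projection_degenerates(rng):
    d = 8
    z = rng.standard_normal((5, d))
    eye = np.eye(d)
    proj = {"wq": rng.standard_normal((d, d)), "wk": rng.standard_normal((d, d)),
            "wv": rng.standard_normal((d, d)), "u_msa": eye}
    expected = self_attention(z @ proj["wq"], z @ proj["wk"], z @ proj["wv"]).data
    np.testing.assert_allclose(multi_head_attention(z, 1, proj).data, expected,
                               atol=1e-12)


def test_multi_head_rejects_indivisible_heads(rng):
    z = rng.standard_normal((4, 10))
    proj = {k: np.eye(10) for k in ("wq", "wk", "wv", "u_msa")}
    with pytest.raises(ValueError):
        multi_head_attention(z, 3, proj)


# ------------------------------------------------------------- CNN block

def test_default_cnn_contract_at_128():
    cfg = CnnBlockConfig.default(128)
    assert cfg.out_channels == 64
    assert cfg.out_spatial(128) == 16  # N=64 tokens of D=256
    block = CnnBlock(cfg, np.random.default_rng(0)).eval()
    img = MoleculeImage(pixels=np.ones((3, 128, 128)), source_smiles="", size=128)
    out = cnn_block(img, block)
    assert out.shape == (64, 16, 16)


def test_cnn_pool_plan_tracks_image_size():
    assert CnnBlockConfig.default(64).out_spatial(64) == 16
    assert CnnBlockConfig.default(256).out_spatial(256) == 16
    assert CnnBlockConfig.default(64, target_spatial=8).out_spatial(64) == 8


def test_cnn_rejects_wrong_input_shape():
    block = CnnBlock(CnnBlockConfig.default(64), np.random.default_rng(0)).eval()
    with pytest.raises(ValueError):
        cnn_block(np.ones((1, 64, 64)), block)


def test_identity_kernel_convolution_oracle(rng):
    """A center-one 3x3 kernel with zero bias reproduces the input patchwise."""
    x = rng.random((1, 1, 4, 4))  # nonnegative, so LeakyReLU is identity
    w = np.zeros((1, 1, 3, 3))
    w[0, 0, 1, 1] = 1.0
    out = Tensor.conv2d(Tensor(x), Tensor(w), Tensor(np.zeros(1)), pad=1)
    np.testing.assert_allclose(out.data, x, atol=1e-12)


def test_leaky_relu_piecewise_definition():
    x = Tensor(np.array([-1.0, 2.0, 0.0]))
    np.testing.assert_allclose(x.leaky_relu(0.01).data, [-0.01, 2.0, 0.0])
    # alpha = 0 degenerates to ReLU
    np.testing.assert_allclose(x.leaky_relu(0.0).data, [0.0, 2.0, 0.0])


# ------------------------------------------------------------- flattening

def test_flatten_channels_as_tokens_row_major():
    w0 = np.array([[[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]])
    flat = flatten_tokens(w0)
    np.testing.assert_array_equal(flat.data, [[1, 2, 3, 4], [5, 6, 7, 8]])
    back = unflatten_tokens(flat, 2, 2)
    np.testing.assert_array_equal(back.data, w0)


def test_flatten_default_config_shape():
    w0 = np.zeros((64, 16, 16))
    assert flatten_tokens(w0).shape == (64, 256)


# ------------------------------------------------------------ encoder layer

def _cfg(**kw):
    base = dict(depth=1, heads=2, token_dim=32, mlp_ratio=2, droppath_rate=0.0)
    base.update(kw)
    return EncoderConfig(**base)


def test_droppath_one_makes_layer_identity(rng):
    layer = EncoderLayer(_cfg(droppath_rate=0.99999), rng)
    layer.rate = 1.0
    layer.train()
    z = rng.standard_normal((6, 32))
    np.testing.assert_allclose(layer(Tensor(z)).data, z, atol=1e-12)


def test_encoder_layer_eval_deterministic(rng):
    layer = EncoderLayer(_cfg(droppath_rate=0.5), rng).eval()
    z = Tensor(rng.standard_normal((6, 32)))
    np.testing.assert_array_equal(layer(z).data, layer(z).data)


def test_encoder_layer_composition_oracle(rng):
    """One eval-mode layer equals explicitly composing LN/MSA/MLP residuals."""
    layer = EncoderLayer(_cfg(), rng).eval()
    z = Tensor(rng.standard_normal((8, 32)))
    a = z + layer.msa(layer.ln1(z))
    expected = (a + layer.mlp(layer.ln2(a))).data
    np.testing.assert_allclose(layer(z).data, expected, atol=1e-10)


def test_encode_depth_zero_adds_positional_encoding(rng):
    z = rng.standard_normal((6, 32))
    out = encode(z, 6, _cfg(depth=0), seed=0)
    np.testing.assert_allclose(out.data, z + positional_encoding(6, 32), atol=1e-12)


@pytest.mark.parametrize("depth", [1, 2, 4])
def test_encode_preserves_shape(rng, depth):
    z = rng.standard_normal((6, 32))
    assert encode(z, 6, _cfg(depth=depth), seed=1).shape == (6, 32)


def test_attention_permutation_equivariance(rng):
    """Without positions, permuting tokens permutes outputs identically."""
    enc = TransformerEncoder(6, _cfg(), np.random.default_rng(3), add_pe=False).eval()
    z = rng.standard_normal((6, 32))
    perm = np.random.default_rng(0).permutation(6)
    out = enc(Tensor(z)).data
    out_perm = enc(Tensor(z[perm])).data
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-5)


def test_encoder_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(heads=3, token_dim=32)
    with pytest.raises(ValueError):
        EncoderConfig(droppath_rate=1.0)
    assert EncoderConfig(heads=8, token_dim=256).head_dim == 32
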