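"""Splitting, loss/metric oracles, forward passes, variants, protocol."""

import dataclasses
import math

import numpy as np
import pytest

from catcpi import ModelConfig, SyntheticSpec, bce_loss, compute_metrics, split_dataset
from catcpi.networks import InteractionNet, count_parameters, make_variant
from catcpi.prot_tokens import build_vocab
from catcpi.train import (TensorData, TrainedModel, bce_logits_graph,
                          bce_loss_graph, forward_cpi, forward_ddi,
                          predict_scores, prepare_data, run_protocol,
                          train_model)


# ----------------------------------------------------------------- split

def test_split_811_exact_sizes():
    records = list(range(1000))
    tr, va, te = split_dataset(records, (8, 1, 1), seed=5)
    assert (len(tr), len(va), len(te)) == (800, 100, 100)


def test_split_disjoint_exhaustive_and_seeded():
    records = [f"r{i}" for i in range(50)]
    a = split_dataset(records, (8, 1, 1), seed=1)
    b = split_dataset(records, (8, 1, 1), seed=1)
    c = split_dataset(records, (8, 1, 1), seed=2)
    assert a == b
    assert [x for part in a for x in part] != records or True  # shuffled
    union = sorted(x for part in a for x in part)
    assert union == sorted(records)
    assert not (set(a[0]) & set(a[1])) and not (set(a[0]) & set(a[2]))
    assert [x for part in a for x in part] != [x for part in c for x in part]
    with pytest.raises(ValueError):
        split_dataset([], seed=0)


# ------------------------------------------------------------------ loss

def test_bce_closed_form_values():
    assert bce_loss([0.5], [1]) == pytest.approx(math.log(2), abs=1e-9)
    assert bce_loss([1.0 - 1e-7], [1]) == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        bce_loss([0.5, 0.5], [1])


def test_bce_matches_elementwise_bruteforce(rng):
    p = rng.uniform(0.01, 0.99, size=20)
    y = rng.integers(0, 2, size=20)
    manual = -sum(yi * math.log(pi) + (1 - yi) * math.log(1 - pi)
                  for pi, yi in zip(p, y)) / 20
    assert bce_loss(p, y) == pytest.approx(manual, abs=1e-8)


def test_graph_losses_agree_with_each_other(rng):
    from catcpi.nn import Tensor

    logits = rng.standard_normal(15)
    y = rng.integers(0, 2, size=15)
    probs = 1 / (1 + np.exp(-logits))
    a = float(bce_loss_graph(Tensor(probs), y).data)
    b = float(bce_logits_graph(Tensor(logits), y).data)
    assert a == pytest.approx(b, abs=1e-9)
    assert a == pytest.approx(bce_loss(probs, y), abs=1e-9)


# --------------------------------------------------------------- metrics

def roc_auc_oracle(scores, labels):
    """Mann-Whitney concordance probability by an O(n^2) pair loop."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def pr_auc_oracle(scores, labels):
    """Step-interpolated precision-recall integration: sum (R_i - R_{i-1}) P_i."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(labels)[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    prev_r, area = 0.0, 0.0
    for p_i, r_i in zip(precision, recall):
        area += (r_i - prev_r) * p_i
        prev_r = r_i
    return area


def test_perfect_and_uninformative_scores():
    y = [0, 1, 0, 1]
    m = compute_metrics(np.array(y, dtype=float), y)
    assert m["roc_auc"] == 1.0 and m["pr_auc"] == 1.0 and m["f1"] == 1.0
    flat = compute_metrics([0.5] * 4, y)
    assert flat["roc_auc"] == 0.5  # tie-averaged


def test_roc_auc_matches_pairwise_concordance(rng):
    scores = rng.random(200)
    labels = rng.integers(0, 2, size=200)
    m = compute_metrics(scores, labels)
    assert m["roc_auc"] == pytest.approx(roc_auc_oracle(scores, labels), abs=1e-10)


def test_pr_auc_matches_step_integration(rng):
    scores = rng.random(150)
    labels = rng.integers(0, 2, size=150)
    m = compute_metrics(scores, labels)
    assert m["pr_auc"] == pytest.approx(pr_auc_oracle(scores, labels), abs=1e-10)


def test_single_class_flags_undefined_aucs():
    m = compute_metrics([0.2, 0.8, 0.6], [1, 1, 1])
    assert not m["auc_defined"]
    assert math.isnan(m["roc_auc"])
    assert m["recall"] == pytest.approx(2 / 3)


# ----------------------------------------------------------- forward pass

@pytest.fixture(scope="module")
def tiny_cpi_model(request):
    from catcpi import gen_cpi_dataset

    ds = gen_cpi_dataset(SyntheticSpec(n_samples=24, positive_fraction=0.5, seed=21))
    cfg = ModelConfig(image_size=32, cnn_target_spatial=8, depth=1, heads=2,
                      fr_hidden=32, droppath_rate=0.0, batch_size=8, epochs=1,
                      seed=21)
    vocab = build_vocab([r.protein_sequence for r in ds.records], cfg.k)
    net = InteractionNet(cfg, vocab_size=len(vocab),
                         rng=np.random.default_rng(0)).eval()
    return TrainedModel(net=net, config=cfg, vocab=vocab), ds


def test_forward_cpi_probability_and_repeatability(tiny_cpi_model):
    model, ds = tiny_cpi_model
    for record in ds.records[:6]:
        p1 = forward_cpi(record, model)
        p2 = forward_cpi(record, model)
        assert 0.0 < p1 < 1.0
        assert p1 == p2


def test_end_to_end_gradient_reaches_both_branches(tiny_cpi_model):
    model, ds = tiny_cpi_model
    net, cfg = model.net, model.config
    net.fr.fc2.w.data[...] = np.random.default_rng(5).standard_normal(
        net.fr.fc2.w.shape).astype(np.float32) * 0.1
    data = prepare_data(ds.records[:4], cfg, model.vocab)
    net.train()
    logits = net.forward_logits(data.images, data.prot_ids)
    bce_logits_graph(logits, data.labels).backward()
    img_params = [p for n, p in net.named_parameters() if n.startswith("cnn.")]
    prot_params = [p for n, p in net.named_parameters() if n.startswith("embedding")]
    assert any(p.grad is not None and np.any(p.grad != 0) for p in img_params)
    assert any(p.grad is not None and np.any(p.grad != 0) for p in prot_params)
    net.eval()


# ------------------------------------------------------------------- DDI

def test_ddi_weight_sharing_bit_identical(ddi_small):
    cfg = ModelConfig(task="ddi", image_size=32, cnn_target_spatial=8, depth=1,
                      heads=2, fr_hidden=32, droppath_rate=0.0, seed=3)
    net = InteractionNet(cfg, rng=np.random.default_rng(3)).eval()
    data = prepare_data(ddi_small.records[:4], cfg, None)
    same = data.images[:1]
    fa = net.compound_features(same).data
    fb = net.compound_features(same).data
    assert np.array_equal(fa, fb)
    record = dataclasses.replace(ddi_small.records[0],
                                 smiles_b=ddi_small.records[0].compound_smiles)
    model = TrainedModel(net=net, config=cfg, vocab=None)
    p = forward_ddi(record, model)
    assert 0.0 < p < 1.0


def test_ddi_encoder_update_affects_both_slots(ddi_small):
    cfg = ModelConfig(task="ddi", image_size=32, cnn_target_spatial=8, depth=1,
                      heads=2, fr_hidden=32, droppath_rate=0.0, seed=3)
    net = InteractionNet(cfg, rng=np.random.default_rng(3)).eval()
    img = prepare_data(ddi_small.records[:1], cfg, None).images
    before_a = net.compound_features(img).data.copy()
    net.cnn.conv0.w.data += 0.05  # perturb the shared encoder
    after_a = net.compound_features(img).data
    after_b = net.compound_features(img).data
    assert not np.array_equal(before_a, after_a)
    assert np.array_equal(after_a, after_b)


# -------------------------------------------------------------- training

def test_lr_zero_leaves_weights_unchanged(cpi_small, tiny_config):
    cfg = dataclasses.replace(tiny_config, learning_rate=0.0, epochs=1)
    tr, va, _ = split_dataset(cpi_small.records, seed=0)
    model = train_model(tr, va, cfg, seed=0)
    fresh = InteractionNet(cfg, vocab_size=len(model.vocab),
                           rng=np.random.default_rng(0))
    for (n1, p1), (n2, p2) in zip(model.net.named_parameters(),
                                  fresh.named_parameters()):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)


def test_training_loss_decreases(cpi_small, tiny_config):
    cfg = dataclasses.replace(tiny_config, epochs=6)
    tr, va, _ = split_dataset(cpi_small.records, seed=1)
    model = train_model(tr, va, cfg, seed=1)
    first, last = model.history[0]["train_loss"], model.history[-1]["train_loss"]
    assert last < first


# -------------------------------------------------------------- variants

@pytest.mark.parametrize("variant", ["full", "no_cnn", "no_trans", "no_p_trans", "no_fr"])
def test_variants_produce_probabilities(variant, cpi_small, tiny_config):
    cfg = dataclasses.replace(tiny_config, variant=variant)
    vocab = build_vocab([r.protein_sequence for r in cpi_small.records], cfg.k)
    net = make_variant(cfg, variant, vocab_size=len(vocab),
                       rng=np.random.default_rng(0)).eval()
    data = prepare_data(cpi_small.records[:4], cfg, vocab)
    p = predict_scores(net, data)
    assert np.all((p > 0) & (p < 1))


def test_no_fr_has_zero_fr_parameters(tiny_config):
    vocab_size = 30
    full = make_variant(tiny_config, "full", vocab_size=vocab_size)
    ablated = make_variant(tiny_config, "no_fr", vocab_size=vocab_size)
    assert count_parameters(full, "fr.") > 0
    assert count_parameters(ablated, "fr.") == 0


def test_no_cnn_patch_count_matches_token_contract(tiny_config):
    net = make_variant(dataclasses.replace(tiny_config, image_size=128,
                                           cnn_target_spatial=16),
                       "no_cnn", vocab_size=30)
    assert net.patches.patch == 16      # (128/16)^2 = 64 = N tokens
    assert net.patches.grid ** 2 == 64
    imgs = np.ones((2, 3, 128, 128), dtype=np.float32)
    assert net.patches(__import__("catcpi.nn", fromlist=["Tensor"]).Tensor(imgs)
                       ).shape == (2, 64, 256)


def test_unknown_variant_rejected(tiny_config):
    with pytest.raises(ValueError):
        make_variant(tiny_config, "no_everything")


# -------------------------------------------------------------- protocol

def test_protocol_single_run_has_zero_std(cpi_small, tiny_config):
    res = run_protocol(cpi_small.records, tiny_config, n_runs=1)
    assert res.selected == 0
    assert all(v == 0.0 for v in res.std.values())


def test_protocol_selects_best_validation_auc(cpi_small, tiny_config):
    res = run_protocol(cpi_small.records, tiny_config, n_runs=2)
    vals = [r["val"]["roc_auc"] for r in res.runs]
    assert res.selected == int(np.argmax(vals))
    assert set(res.mean) == {"roc_auc", "pr_auc", "precision", "recall", "f1"}
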