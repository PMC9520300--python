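"""Loss, metrics, splitting, the training loop, the five-run protocol, and
the robustness harness.

Training minimizes binary cross-entropy with Adam (lr 0.001, batch size 128
by default).  Datasets are split 8:1:1 into train/validation/test; the
published protocol runs five independently seeded trainings, selects the
model with the best validation ROC-AUC, and reports mean +/- standard
deviation of the test metrics across runs.  The k-gram vocabulary is always
built from the training split only, so no test k-mer leaks into the corpus.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (average_precision_score, precision_score,
                             recall_score, roc_auc_score)

from .config import ModelConfig
from .mol_image import apply_transform, plan_transform, render_batch
from .networks import InteractionNet
from .nn import Adam, Tensor
from .prot_tokens import KgramVocab, build_vocab, encode_batch
from .synthetic import InteractionRecord

EPS = 1e-7


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


# ------------------------------------------------------------------ split

def split_dataset(records, ratios=(8, 1, 1), seed: int = 0):
    """Disjoint, exhaustive, seed-shuffled split; for 8:1:1 the sizes are
    floor(0.8 n) / floor(0.1 n) / remainder."""
    records = list(records)
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    r = np.asarray(ratios, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    r = r / r.sum()
    n_train, n_val = int(np.floor(r[0] * n)), int(np.floor(r[1] * n))
    perm = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in perm[:n_train]]
    val = [records[i] for i in perm[n_train:n_train + n_val]]
    test = [records[i] for i in perm[n_train + n_val:]]
    return train, val, test


# ------------------------------------------------------------ loss/metrics

def bce_loss(probs, labels) -> float:
    """Mean binary cross-entropy, probabilities clipped to [eps, 1-eps]."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    p = np.clip(probs, EPS, 1.0 - EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def bce_loss_graph(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Autograd-tracked BCE on a probability tensor."""
    y = np.asarray(labels, dtype=probs.data.dtype)
    p = probs.clip(EPS, 1.0 - EPS)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


def bce_logits_graph(logits: Tensor, labels: np.ndarray) -> Tensor:
    """BCE computed from logits: mean(softplus(l) - y*l).  Identical value to
    ``bce_loss_graph(sigmoid(l), y)`` but numerically stable when predictions
    saturate, so training gradients never vanish at the clip boundary."""
    y = np.asarray(labels, dtype=logits.data.dtype)
    return (logits.softplus() - y * logits).mean()


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """ROC-AUC (rank-based, tie-averaged), PR-AUC (step-interpolated),
    precision/recall/F1 at the threshold.  With single-class labels the AUCs
    are undefined and flagged."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    preds = (scores >= threshold).astype(int)
    both_classes = 0 < labels.sum() < len(labels)
    prec = precision_score(labels, preds, zero_division=0)
    rec = recall_score(labels, preds, zero_division=0)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    out = {
        "roc_auc": float(roc_auc_score(labels, scores)) if both_classes else float("nan"),
        "pr_auc": float(average_precision_score(labels, scores)) if both_classes else float("nan"),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "auc_defined": bool(both_classes),
    }
    return out


# ---------------------------------------------------------- data plumbing

@dataclass
class TensorData:
    """Device-ready arrays for one split."""

    images: np.ndarray                   # (n, 3, S, S) float32
    labels: np.ndarray                   # (n,) int
    prot_ids: np.ndarray | None = None   # (n, N) int, CPI
    images_b: np.ndarray | None = None   # (n, 3, S, S) float32, DDI

    def __len__(self):
        return len(self.labels)


def prepare_data(records, config: ModelConfig, vocab: KgramVocab | None = None,
                 cache: dict | None = None) -> TensorData:
    records = list(records)
    labels = np.array([r.label for r in records], dtype=int)
    images = render_batch([r.compound_smiles for r in records], config.image_size, cache)
    if config.task == "cpi":
        if vocab is None:
            raise ValueError("CPI data preparation requires a vocabulary")
        ids = encode_batch([r.protein_sequence for r in records], vocab,
                           config.n_tokens, config.protein_subsample)
        return TensorData(images=images, labels=labels, prot_ids=ids)
    images_b = render_batch([r.smiles_b for r in records], config.image_size, cache)
    return TensorData(images=images, labels=labels, images_b=images_b)


def _forward(net: InteractionNet, data: TensorData, idx: np.ndarray) -> Tensor:
    if net.config.task == "cpi":
        return net(data.images[idx], data.prot_ids[idx])
    return net(data.images[idx], data.images_b[idx])


def _forward_logits(net: InteractionNet, data: TensorData, idx: np.ndarray) -> Tensor:
    if net.config.task == "cpi":
        return net.forward_logits(data.images[idx], data.prot_ids[idx])
    return net.forward_logits(data.images[idx], data.images_b[idx])


def predict_scores(net: InteractionNet, data: TensorData, batch: int = 256) -> np.ndarray:
    from .nn import no_grad

    net.eval()
    out = np.empty(len(data), dtype=np.float64)
    with no_grad():
        for lo in range(0, len(data), batch):
            idx = np.arange(lo, min(lo + batch, len(data)))
            out[idx] = _forward(net, data, idx).data
    return out


# -------------------------------------------------------------- training

@dataclass
class TrainedModel:
    net: InteractionNet
    config: ModelConfig
    vocab: KgramVocab | None
    history: list = field(default_factory=list)
    best_epoch: int = -1

    def predict_records(self, records, cache: dict | None = None) -> np.ndarray:
        data = prepare_data(records, self.config, self.vocab, cache)
        return predict_scores(self.net, data)


def forward_cpi(record: InteractionRecord, model: TrainedModel,
                training: bool = False) -> float:
    """Probability for a single compound/protein record."""
    data = prepare_data([record], model.config, model.vocab)
    model.net.train(training)
    p = float(_forward(model.net, data, np.array([0])).data[0])
    model.net.eval()
    return p


def forward_ddi(record: InteractionRecord, model: TrainedModel,
                training: bool = False) -> float:
    """Probability for a single drug-pair record (shared compound encoder)."""
    return forward_cpi(record, model, training)


def train_model(train_records, val_records, config: ModelConfig,
                seed: int | None = None, cache: dict | None = None,
                log=None, stop_when=None) -> TrainedModel:
    """Adam/BCE training with per-epoch validation and best-AUC checkpointing.

    ``stop_when(net, epoch_entry)`` may end training early (e.g. once a target
    training metric is reached); ``config.epochs`` is the maximum.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cache = {} if cache is None else cache

    vocab = None
    if config.task == "cpi":
        vocab = build_vocab([r.protein_sequence for r in train_records], config.k)
    tr = prepare_data(train_records, config, vocab, cache)
    va = prepare_data(val_records, config, vocab, cache) if len(val_records) else None

    return _train_on_prepared(tr, va, config, seed, vocab, log=log,
                              stop_when=stop_when)


# ------------------------------------------------------------- protocol

@dataclass
class RunResult:
    """Outcome of the multi-run protocol: per-run metrics, the run selected
    by validation ROC-AUC, and mean/std of test metrics across runs."""

    runs: list
    selected: int
    mean: dict
    std: dict
    config: dict

    def to_json(self, indent=None) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)


_METRIC_KEYS = ("roc_auc", "pr_auc", "precision", "recall", "f1")


def run_protocol(records, config: ModelConfig, n_runs: int = 5,
                 cache: dict | None = None) -> RunResult:
    """Run n independently seeded train/evaluate cycles (re-split and
    re-initialized per run), select the best by validation ROC-AUC, and
    aggregate test metrics."""
    cache = {} if cache is None else cache
    seeds = [int(s) for s in
             np.random.SeedSequence(config.seed).generate_state(n_runs) % (2**31)]
    runs = []
    for i, seed in enumerate(seeds):
        train, val, test = split_dataset(records, (8, 1, 1), seed=seed)
        model = train_model(train, val, config, seed=seed, cache=cache)
        te = prepare_data(test, config, model.vocab, cache)
        va = prepare_data(val, config, model.vocab, cache)
        runs.append({
            "run": i, "seed": seed,
            "val": compute_metrics(predict_scores(model.net, va), va.labels),
            "test": compute_metrics(predict_scores(model.net, te), te.labels),
        })
    selected = int(np.argmax([r["val"]["roc_auc"] for r in runs]))
    mean = {k: float(np.mean([r["test"][k] for r in runs])) for k in _METRIC_KEYS}
    std = {k: float(np.std([r["test"][k] for r in runs])) for k in _METRIC_KEYS}
    return RunResult(runs=runs, selected=selected, mean=mean, std=std,
                     config=config.to_dict())


# ------------------------------------------------------------ robustness

def _transform_images(images: np.ndarray, plan, size) -> np.ndarray:
    from .mol_image import MoleculeImage

    out = np.empty_like(images)
    s = images.shape[-1]
    for i, lab in enumerate(plan.assignment):
        img = MoleculeImage(pixels=images[i].astype(np.float64), source_smiles="", size=s)
        out[i] = apply_transform(img, lab, size).pixels.astype(images.dtype)
    return out


def robustness_experiment(records, config: ModelConfig, method: str,
                          size: tuple[int, int] | None = None,
                          seed: int = 0) -> dict:
    """Train on pristine depictions, then re-train after transforming every
    compound image by the given protocol; report both test ROC-AUCs and the
    delta.  No numeric bound is asserted — deltas are data-dependent."""
    train, val, test = split_dataset(records, (8, 1, 1), seed=seed)
    cache: dict = {}
    baseline = train_model(train, val, config, seed=seed, cache=cache)
    te = prepare_data(test, config, baseline.vocab, cache)
    base_auc = compute_metrics(predict_scores(baseline.net, te), te.labels)["roc_auc"]

    vocab = baseline.vocab
    splits = {"train": train, "val": val, "test": test}
    offsets = {"train": 1, "val": 2, "test": 3}
    data = {k: prepare_data(v, config, vocab, cache) for k, v in splits.items()}
    for k, d in data.items():
        plan = plan_transform(len(d), method, size=size, seed=seed + offsets[k])
        d.images = _transform_images(d.images, plan, size)

    model_t = _train_on_prepared(data["train"], data["val"], config, seed, vocab)
    t_auc = compute_metrics(predict_scores(model_t.net, data["test"]),
                            data["test"].labels)["roc_auc"]
    return {"method": method, "baseline_roc_auc": float(base_auc),
            "transformed_roc_auc": float(t_auc), "delta": float(t_auc - base_auc)}


def _train_on_prepared(tr: TensorData, va: TensorData | None, config: ModelConfig,
                       seed: int, vocab, log=None, stop_when=None) -> TrainedModel:
    rng = np.random.default_rng(seed)
    net = InteractionNet(config, vocab_size=len(vocab) if vocab else None,
                         rng=np.random.default_rng(seed))
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history, best_auc, best_state, best_epoch = [], -np.inf, None, -1
    for epoch in range(config.epochs):
        net.train()
        order = rng.permutation(len(tr))
        losses = []
        for lo in range(0, len(tr), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            loss = bce_logits_graph(_forward_logits(net, tr, idx), tr.labels[idx])
            if not np.isfinite(loss.data):
                raise TrainingDiverged(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if va is not None:
            vm = compute_metrics(predict_scores(net, va), va.labels)
            entry["val"] = vm
            score = vm["roc_auc"] if vm["auc_defined"] else -bce_loss(
                predict_scores(net, va), va.labels)
            if score > best_auc:
                best_auc, best_state, best_epoch = score, net.state_dict(), epoch
        history.append(entry)
        if log:
            log(entry)
        if stop_when is not None and stop_when(net, entry):
            break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return TrainedModel(net=net, config=config, vocab=vocab, history=history,
                        best_epoch=best_epoch)
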