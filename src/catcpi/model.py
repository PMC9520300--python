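"""Model/Results facade over the training machinery.

`InteractionModel` is built from interaction records (or a DataFrame / TSV)
plus a `ModelConfig`; `fit()` trains one network on an 8:1:1 split and
returns `InteractionResults` carrying the trained parameters, per-epoch
history, validation/test metrics, a `summary()` table and `predict()`.
`fit_protocol()` runs the multi-seed selection protocol and returns
`ProtocolResults` with per-run metrics and mean +/- std aggregates.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .networks import InteractionNet, count_parameters
from .prot_tokens import KgramVocab
from .synthetic import InteractionRecord, SyntheticDataset, read_tsv
from .train import (RunResult, TrainedModel, compute_metrics, predict_scores,
                    prepare_data, run_protocol, split_dataset, train_model)

CHECKPOINT_VERSION = 1


class InteractionModel:
    """Compound-protein (or drug-drug) interaction model bound to a dataset."""

    def __init__(self, records, config: ModelConfig | None = None):
        if isinstance(records, SyntheticDataset):
            if config is None:
                config = ModelConfig(task=records.task)
            records = records.records
        self.records = list(records)
        if not self.records:
            raise ValueError("no records supplied")
        inferred = "ddi" if self.records[0].smiles_b is not None else "cpi"
        self.config = config if config is not None else ModelConfig(task=inferred)
        if self.config.task != inferred:
            raise ValueError(f"records look like {inferred!r} but config.task is "
                             f"{self.config.task!r}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ModelConfig | None = None):
        if "protein_sequence" in df.columns:
            recs = [InteractionRecord(compound_smiles=r.compound_smiles,
                                      protein_sequence=r.protein_sequence,
                                      label=int(r.label)) for r in df.itertuples()]
        else:
            recs = [InteractionRecord(compound_smiles=r.smiles_a, smiles_b=r.smiles_b,
                                      label=int(r.label)) for r in df.itertuples()]
        return cls(recs, config)

    @classmethod
    def from_tsv(cls, path, config: ModelConfig | None = None):
        return cls(read_tsv(path), config)

    def fit(self, seed: int | None = None, log=None) -> "InteractionResults":
        seed = self.config.seed if seed is None else seed
        train, val, test = split_dataset(self.records, (8, 1, 1), seed=seed)
        cache: dict = {}
        trained = train_model(train, val, self.config, seed=seed, cache=cache, log=log)
        va = prepare_data(val, self.config, trained.vocab, cache)
        te = prepare_data(test, self.config, trained.vocab, cache)
        val_metrics = compute_metrics(predict_scores(trained.net, va), va.labels)
        test_metrics = compute_metrics(predict_scores(trained.net, te), te.labels)
        return InteractionResults(trained, val_metrics, test_metrics, seed=seed)

    def fit_protocol(self, n_runs: int = 5) -> "ProtocolResults":
        return ProtocolResults(run_protocol(self.records, self.config, n_runs=n_runs))


class InteractionResults:
    def __init__(self, trained: TrainedModel, val_metrics: dict, test_metrics: dict,
                 seed: int):
        self.model = trained
        self.config = trained.config
        self.history = trained.history
        self.val_metrics = val_metrics
        self.test_metrics = test_metrics
        self.seed = seed

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.model.net)

    def predict(self, records) -> np.ndarray:
        return self.model.predict_records(records)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Interaction model results",
            "=" * 58,
            f"task: {cfg.task:<12} variant: {cfg.variant:<12} seed: {self.seed}",
            f"image {cfg.image_size}px  k={cfg.k}  N={cfg.n_tokens}  D={cfg.token_dim}"
            f"  depth={cfg.depth}  heads={cfg.heads}",
            f"parameters: {self.n_parameters:,}   epochs: {cfg.epochs}"
            f"   best epoch: {self.model.best_epoch}",
            "-" * 58,
            f"{'metric':<12}{'validation':>14}{'test':>14}",
        ]
        for k in ("roc_auc", "pr_auc", "precision", "recall", "f1"):
            lines.append(f"{k:<12}{self.val_metrics[k]:>14.4f}{self.test_metrics[k]:>14.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = [h["epoch"] for h in self.history]
        ax.plot(epochs, [h["train_loss"] for h in self.history], label="train loss")
        if self.history and "val" in self.history[0]:
            ax.plot(epochs, [h["val"]["roc_auc"] for h in self.history],
                    label="val ROC-AUC")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def save(self, path):
        save_checkpoint(self.model, path)


class ProtocolResults:
    def __init__(self, result: RunResult):
        self.result = result
        self.runs = result.runs
        self.selected = result.selected
        self.mean = result.mean
        self.std = result.std

    def summary(self) -> str:
        lines = ["Multi-run protocol results", "=" * 58,
                 f"runs: {len(self.runs)}   selected (best val ROC-AUC): run {self.selected}",
                 "-" * 58, f"{'metric':<12}{'mean':>12}{'std':>12}{'selected':>12}"]
        sel = self.runs[self.selected]["test"]
        for k in ("roc_auc", "pr_auc", "precision", "recall", "f1"):
            lines.append(f"{k:<12}{self.mean[k]:>12.4f}{self.std[k]:>12.4f}{sel[k]:>12.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_json(self, indent=None) -> str:
        return self.result.to_json(indent=indent)


# ---------------------------------------------------------------- checkpoint

def save_checkpoint(model: TrainedModel, path):
    """Self-describing versioned checkpoint: weights + config + vocabulary."""
    payload = {f"param:{k}": v for k, v in model.net.state_dict().items()}
    meta = {"version": CHECKPOINT_VERSION, "config": model.config.to_dict(),
            "best_epoch": model.best_epoch}
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if model.vocab is not None:
        buf = io.StringIO()
        buf.write(f"#k={model.vocab.k}\n")
        for kmer, idx in model.vocab.token_to_id.items():
            buf.write(f"{kmer}\t{idx}\n")
        payload["vocab"] = np.frombuffer(buf.getvalue().encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        config = ModelConfig.from_dict(meta["config"])
        vocab = None
        if "vocab" in z.files:
            lines = bytes(z["vocab"]).decode().splitlines()
            k = int(lines[0].split("=", 1)[1])
            mapping = {}
            for line in lines[1:]:
                kmer, idx = line.split("\t")
                mapping[kmer] = int(idx)
            vocab = KgramVocab(k=k, token_to_id=mapping)
        net = InteractionNet(config, vocab_size=len(vocab) if vocab else None)
        net.load_state_dict({k[len("param:"):]: z[k] for k in z.files
                             if k.startswith("param:")})
        net.eval()
    return TrainedModel(net=net, config=config, vocab=vocab,
                        best_epoch=meta["best_epoch"])
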