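"""Synthetic CPI/DDI datasets with a planted, perfectly learnable rule.

Real interaction tables (compound SMILES, protein sequence, binary label) are
emulated by template-generated drug-like molecules and random protein
sequences.  Labels come from a *planted rule* — a deterministic function of
the record (a designated substructure token in the SMILES co-occurring with a
designated 4-mer motif in the protein, or two tokens across a drug pair) — so
a non-learned oracle separates classes perfectly: any end-to-end learning
failure is a model defect, not label noise.

Compounds are instantiated from a built-in set of 56 drug-like scaffolds with
randomized substituents, which guarantees every SMILES parses and renders.
Positive counts are exact by construction, and a fixed spec regenerates a
byte-identical dataset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_RESIDUE = "X"

#: scaffold templates; "{}" marks the substitution point
SCAFFOLDS = (
    "c1ccc({})cc1", "Cc1ccc({})cc1", "COc1ccc({})cc1", "Fc1ccc({})cc1",
    "Clc1ccc({})cc1", "Cc1cc({})ccc1C", "c1ccc2cc({})ccc2c1", "c1ccc(-c2ccc({})cc2)cc1",
    "c1ccc({})nc1", "c1ccc({})cn1", "c1cnc({})cn1", "c1ccnc({})c1",
    "c1cc({})cc(C)c1", "c1cc({})oc1", "c1cc({})sc1", "c1cc({})[nH]c1",
    "c1cc({})on1", "c1cc({})cs1", "Cn1ccc({})c1", "c1csc({})n1",
    "c1occ({})c1", "CC1CCC({})CC1", "C1CCC({})CC1", "C1CCC({})CCC1",
    "C1CN({})CCN1C", "C1CCN({})CC1", "C1CCC({})OC1", "O1CCC({})CC1",
    "C1CSC({})C1", "c1ccc2[nH]c({})cc2c1", "c1ccc2oc({})cc2c1", "c1ccc2sc({})cc2c1",
    "c1ccc2nc({})ccc2c1", "c1cc({})cc2c1OCO2", "Cc1noc({})n1", "Cc1nnc({})s1",
    "Cc1ccc({})nn1", "c1cnn({})c1", "Cn1cnc({})c1", "c1cc({})c2[nH]ccc2c1",
    "CC(C)c1ccc({})cc1", "CCOc1ccc({})cc1", "Cc1ccc({})o1", "Cc1ccc({})s1",
    "CC1CC({})CC(C)O1", "Cc1cnc({})cn1", "OCc1ccc({})cc1", "NCc1ccc({})cc1",
    "CC(=O)c1ccc({})cc1", "c1ccc(C({})=O)cc1", "c1ccc(O{})cc1", "c1ccc(N{})cc1",
    "c1ccc(C{})cc1", "Cc1cccc({})c1N", "CSc1ccc({})cc1", "Cc1cc({})no1",
)

#: substituents; "C(=O)O" / "C(F)(F)F" / "C#N" double as planted-rule tokens
SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)N",
    "S(C)(=O)=O", "CO", "CN", "OC(C)C",
)

_MAX_RESAMPLE = 500


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedRule:
    """Deterministic label function recorded with every synthetic dataset."""

    rule_id: str
    compound_token: str = "C(=O)O"
    protein_motif: str = "WYKH"
    token_a: str = "C(F)(F)F"
    token_b: str = "C#N"

    def fires_cpi(self, smiles: str, protein: str) -> bool:
        return self.compound_token in smiles and self.protein_motif in protein

    def fires_ddi(self, smiles_a: str, smiles_b: str) -> bool:
        return self.token_a in smiles_a and self.token_b in smiles_b


@dataclass(frozen=True)
class InteractionRecord:
    compound_smiles: str
    label: int
    protein_sequence: str | None = None
    smiles_b: str | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int
    positive_fraction: float = 0.5
    protein_length_range: tuple[int, int] = (100, 300)
    unknown_residue_rate: float = 0.0
    rule_id: str = "motif"
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0, 1)")
        lo, hi = self.protein_length_range
        if lo > hi or lo < 4:
            raise ValueError("invalid protein_length_range")
        if not (0.0 <= self.unknown_residue_rate <= 0.1):
            raise ValueError("unknown_residue_rate must lie in [0, 0.1]")

    @property
    def n_positive(self) -> int:
        return int(np.floor(self.n_samples * self.positive_fraction + 0.5))


@dataclass
class SyntheticDataset:
    records: list[InteractionRecord]
    rule: PlantedRule
    spec: SyntheticSpec
    task: str = "cpi"

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def oracle_scores(self) -> np.ndarray:
        """Apply the planted rule directly (no learning): 1.0 where it fires."""
        if self.task == "cpi":
            return np.array([float(self.rule.fires_cpi(r.compound_smiles, r.protein_sequence))
                             for r in self.records])
        return np.array([float(self.rule.fires_ddi(r.compound_smiles, r.smiles_b))
                         for r in self.records])

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def _one_smiles(rng: np.random.Generator) -> str:
    scaf = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
    sub = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
    return scaf.format(sub)


def gen_compounds(n: int, seed: int) -> list[str]:
    """n template-instantiated, parseable, depictable SMILES (deterministic)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [_one_smiles(rng) for _ in range(n)]


def _one_protein(rng: np.random.Generator, lo: int, hi: int, unknown_rate: float) -> str:
    length = int(rng.integers(lo, hi + 1))
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    seq = np.array(list(AMINO_ACIDS))[idx]
    if unknown_rate > 0:
        mask = rng.random(length) < unknown_rate
        seq[mask] = UNKNOWN_RESIDUE
    return "".join(seq)


def gen_proteins(n: int, length_range: tuple[int, int], unknown_rate: float,
                 seed: int) -> list[str]:
    """n sequences over the 20 standard residues, lengths uniform on the
    range, each position independently replaced by 'X' at `unknown_rate`."""
    lo, hi = length_range
    if n < 1 or lo > hi or lo < 1:
        raise ValueError("invalid arguments to gen_proteins")
    if not (0.0 <= unknown_rate <= 0.1):
        raise ValueError("unknown_rate must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    return [_one_protein(rng, lo, hi, unknown_rate) for _ in range(n)]


def _splice_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif):]


def gen_cpi_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Compound/protein/label records with exactly ``spec.n_positive``
    positives under the planted rule (compound token AND protein motif)."""
    rule = PlantedRule(rule_id=spec.rule_id)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.protein_length_range
    labels = np.zeros(spec.n_samples, dtype=int)
    labels[: spec.n_positive] = 1
    rng.shuffle(labels)
    records = []
    for y in labels:
        if y == 1:
            for _ in range(_MAX_RESAMPLE):
                smi = _one_smiles(rng)
                if rule.compound_token in smi:
                    break
            else:
                raise GenerationError(f"rule {spec.rule_id!r}: no token-bearing compound "
                                      f"after {_MAX_RESAMPLE} draws")
            prot = _splice_motif(_one_protein(rng, lo, hi, spec.unknown_residue_rate),
                                 rule.protein_motif, rng)
            assert rule.fires_cpi(smi, prot)
        else:
            for _ in range(_MAX_RESAMPLE):
                smi = _one_smiles(rng)
                prot = _one_protein(rng, lo, hi, spec.unknown_residue_rate)
                if not rule.fires_cpi(smi, prot):
                    break
            else:
                raise GenerationError(f"rule {spec.rule_id!r}: could not draw a negative "
                                      f"after {_MAX_RESAMPLE} attempts")
        records.append(InteractionRecord(compound_smiles=smi, protein_sequence=prot,
                                         label=int(y)))
    return SyntheticDataset(records=records, rule=rule, spec=spec, task="cpi")


def gen_ddi_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Drug-pair records; the rule fires on co-occurrence of two tokens."""
    rule = PlantedRule(rule_id=spec.rule_id)
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.n_samples, dtype=int)
    labels[: spec.n_positive] = 1
    rng.shuffle(labels)
    records = []
    for y in labels:
        if y == 1:
            for _ in range(_MAX_RESAMPLE):
                a = _one_smiles(rng)
                if rule.token_a in a:
                    break
            else:
                raise GenerationError(f"rule {spec.rule_id!r}: token_a unreachable")
            for _ in range(_MAX_RESAMPLE):
                b = _one_smiles(rng)
                if rule.token_b in b:
                    break
            else:
                raise GenerationError(f"rule {spec.rule_id!r}: token_b unreachable")
        else:
            for _ in range(_MAX_RESAMPLE):
                a, b = _one_smiles(rng), _one_smiles(rng)
                if not rule.fires_ddi(a, b):
                    break
            else:
                raise GenerationError(f"rule {spec.rule_id!r}: negative unreachable")
        records.append(InteractionRecord(compound_smiles=a, smiles_b=b, label=int(y)))
    return SyntheticDataset(records=records, rule=rule, spec=spec, task="ddi")


# ----------------------------------------------------------------------- I/O

def to_dataframe(ds: SyntheticDataset | list[InteractionRecord]) -> pd.DataFrame:
    records = ds.records if isinstance(ds, SyntheticDataset) else ds
    if records and records[0].protein_sequence is not None:
        return pd.DataFrame({
            "compound_smiles": [r.compound_smiles for r in records],
            "protein_sequence": [r.protein_sequence for r in records],
            "label": [r.label for r in records]})
    return pd.DataFrame({
        "smiles_a": [r.compound_smiles for r in records],
        "smiles_b": [r.smiles_b for r in records],
        "label": [r.label for r in records]})


def write_tsv(ds, path: str | Path):
    to_dataframe(ds).to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t")
    if "protein_sequence" in df.columns:
        return [InteractionRecord(compound_smiles=r.compound_smiles,
                                  protein_sequence=r.protein_sequence, label=int(r.label))
                for r in df.itertuples()]
    return [InteractionRecord(compound_smiles=r.smiles_a, smiles_b=r.smiles_b,
                              label=int(r.label))
            for r in df.itertuples()]


def protein_id(seq: str) -> str:
    """Stable FASTA record id: truncated SHA-1 of the sequence."""
    return hashlib.sha1(seq.encode()).hexdigest()[:12]


def write_fasta(ds: SyntheticDataset | list[InteractionRecord], path: str | Path):
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = ds.records if isinstance(ds, SyntheticDataset) else ds
    seen, out = set(), []
    for r in records:
        if r.protein_sequence and r.protein_sequence not in seen:
            seen.add(r.protein_sequence)
            out.append(SeqRecord(Seq(r.protein_sequence), id=protein_id(r.protein_sequence),
                                 description=""))
    seqio_write(out, str(path), "fasta")
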