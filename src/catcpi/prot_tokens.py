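"""k-gram protein tokenization.

A protein over the 20 standard one-letter residues (plus 'X' for the single
unknown class) is segmented by a stride-1 sliding window into overlapping
k-mers; a vocabulary ("corpus") built from the training sequences numbers
each distinct k-mer, raising the effective alphabet from 20 residues to up to
20^k sub-sequence types.  A sequence is encoded to a fixed length N: shorter
sequences are padded, longer ones are subsampled at evenly spaced window
start positions (length-proportional subsampling), and the resulting ids are
embedded into R^D by a learned table whose pad row is zero-initialized.

Reserved ids: 0 = pad, 1 = unknown (novel k-mers at test time and any k-mer
containing a non-standard residue).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic import AMINO_ACIDS

PAD_ID = 0
UNK_ID = 1
N_RESERVED = 2

_STANDARD = set(AMINO_ACIDS)


@dataclass(frozen=True)
class KgramVocab:
    k: int
    token_to_id: dict

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def __len__(self):
        return N_RESERVED + len(self.token_to_id)

    def lookup(self, kmer: str) -> int:
        if any(ch not in _STANDARD for ch in kmer):
            return UNK_ID
        return self.token_to_id.get(kmer, UNK_ID)

    def save_tsv(self, path: str | Path):
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for kmer, idx in self.token_to_id.items():
                fh.write(f"{kmer}\t{idx}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "KgramVocab":
        mapping = {}
        with open(path) as fh:
            header = fh.readline().strip()
            k = int(header.split("=", 1)[1])
            for line in fh:
                kmer, idx = line.rstrip("\n").split("\t")
                mapping[kmer] = int(idx)
        return cls(k=k, token_to_id=mapping)


@dataclass(frozen=True)
class ProteinTokens:
    ids: np.ndarray  # length-N int vector
    n_real: int      # count of non-pad entries; pads occupy the tail

    def __post_init__(self):
        if np.any(self.ids[self.n_real:] != PAD_ID):
            raise ValueError("pad ids must occupy exactly the trailing positions")


def kgram_segments(seq: str, k: int) -> list[str]:
    """All stride-1 windows of length k: exactly len(seq) - k + 1 of them."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than window k={k}")
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


def build_vocab(train_seqs: list[str], k: int) -> KgramVocab:
    """Vocabulary over k-mers observed in training sequences, numbered in
    first-occurrence order after the two reserved ids.  k-mers containing a
    non-standard residue are excluded (they map to the unknown id)."""
    if not train_seqs:
        raise ValueError("cannot build a vocabulary from an empty training set")
    mapping: dict[str, int] = {}
    for seq in train_seqs:
        for kmer in kgram_segments(seq, k):
            if kmer not in mapping and all(ch in _STANDARD for ch in kmer):
                mapping[kmer] = N_RESERVED + len(mapping)
    return KgramVocab(k=k, token_to_id=mapping)


def subsample_positions(n_windows: int, n_out: int) -> np.ndarray:
    """Evenly spaced start positions round(j*(W-1)/(N-1)), order-preserving;
    first = 0, last = W-1."""
    if n_out == 1:
        return np.array([0])
    j = np.arange(n_out)
    return np.floor(j * (n_windows - 1) / (n_out - 1) + 0.5).astype(int)


def encode_protein(seq: str, vocab: KgramVocab, n_tokens: int,
                   mode: str = "even") -> ProteinTokens:
    """Fixed-length encoding: all windows then pad if they fit, otherwise
    length-proportional subsampling ("even") or plain truncation."""
    windows = kgram_segments(seq, vocab.k)
    w = len(windows)
    ids = np.full(n_tokens, PAD_ID, dtype=np.int64)
    if w <= n_tokens:
        ids[:w] = [vocab.lookup(x) for x in windows]
        n_real = w
    elif mode == "even":
        pos = subsample_positions(w, n_tokens)
        ids[:] = [vocab.lookup(windows[p]) for p in pos]
        n_real = n_tokens
    elif mode == "truncate":
        ids[:] = [vocab.lookup(x) for x in windows[:n_tokens]]
        n_real = n_tokens
    else:
        raise ValueError(f"unknown subsample mode {mode!r}")
    return ProteinTokens(ids=ids, n_real=n_real)


def encode_batch(seqs: list[str], vocab: KgramVocab, n_tokens: int,
                 mode: str = "even") -> np.ndarray:
    return np.stack([encode_protein(s, vocab, n_tokens, mode).ids for s in seqs])


def embed_tokens(tokens: ProteinTokens | np.ndarray, table):
    """Row j of the output is table[ids[j]] (autograd-tracked gather)."""
    from .nn import Tensor, as_tensor

    ids = tokens.ids if isinstance(tokens, ProteinTokens) else np.asarray(tokens)
    table = as_tensor(table) if not isinstance(table, Tensor) else table
    if int(ids.max(initial=0)) >= table.data.shape[0]:
        raise IndexError("token id out of embedding-table range")
    return Tensor.embedding(table, ids)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA id -> sequence, via Biopython."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
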