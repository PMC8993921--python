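"""Aligned-family I/O, one-hot encoding and alignment preprocessing.

Two preprocessing transforms that shape the learned representation are
implemented here: query-centric column removal (drop alignment columns
where a designated query sequence has a gap) and density-based sequence
reweighting (down-weight sequences with many near-identical neighbors,
the standard correction for uneven sampling of a family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from famgeo.alphabet import Alphabet, PROTEIN


@dataclass
class AlignedFamily:
    """A multiple sequence alignment stored as an N x L integer code matrix."""

    ids: list
    rows: np.ndarray  # (N, L) int codes into alphabet.symbols
    alphabet: Alphabet = PROTEIN
    query_id: str | None = None

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.ndim != 2:
            raise ValueError("rows must be a 2-D matrix")
        if len(self.ids) != self.rows.shape[0]:
            raise ValueError("ids and rows disagree on the number of sequences")
        if self.rows.size and (self.rows.min() < 0 or self.rows.max() >= self.alphabet.C):
            raise ValueError("row codes outside alphabet range")
        if self.query_id is not None and self.query_id not in self.ids:
            raise KeyError(f"query_id {self.query_id!r} not among sequence ids")

    @property
    def N(self) -> int:
        return self.rows.shape[0]

    @property
    def L(self) -> int:
        return self.rows.shape[1]

    @property
    def onehot(self) -> np.ndarray:
        """One-hot view of shape (N, L, C); each row-position sums to 1."""
        return np.eye(self.alphabet.C, dtype=np.float64)[self.rows]

    def sequence(self, seq_id: str) -> np.ndarray:
        return self.rows[self.index_of(seq_id)]

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def as_strings(self) -> list:
        return [self.alphabet.decode(r) for r in self.rows]

    @classmethod
    def from_strings(
        cls,
        ids,
        seqs,
        alphabet: Alphabet = PROTEIN,
        query_id: str | None = None,
    ) -> "AlignedFamily":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            bad = next(i for i, s in zip(ids, seqs) if len(s) != len(seqs[0]))
            raise ValueError(f"ragged alignment: record {bad!r} has a different length")
        rows = np.stack([alphabet.encode(s) for s in seqs]) if seqs else np.zeros((0, 0), int)
        return cls(list(ids), rows, alphabet, query_id)


@dataclass
class SequenceWeights:
    """Per-sequence weights from density-based reweighting."""

    ids: list
    w: np.ndarray
    identity_threshold: float = 0.8

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.any(self.w <= 0) or np.any(self.w > 1):
            raise ValueError("weights must lie in (0, 1]")

    def to_tsv(self, path):
        with open(path, "w") as fh:
            for i, wi in zip(self.ids, self.w):
                fh.write(f"{i}\t{wi:.8g}\n")


def read_alignment(path, fmt: str = "fasta", alphabet: Alphabet = PROTEIN) -> AlignedFamily:
    """Read an aligned FASTA or Stockholm file into an :class:`AlignedFamily`.

    All records must have equal length; '.' and '-' both parse as the gap,
    residues are case-insensitive, and ambiguity codes map per the alphabet.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"no records found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    L0 = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != L0:
            raise ValueError(
                f"ragged alignment: record {rid!r} has length {len(s)}, expected {L0}"
            )
    return AlignedFamily.from_strings(ids, seqs, alphabet)


def write_alignment(family: AlignedFamily, path) -> None:
    """Write an aligned FASTA file."""
    with open(path, "w") as fh:
        for rid, seq in zip(family.ids, family.as_strings()):
            fh.write(f">{rid}\n{seq}\n")


def query_centric_reduce(family: AlignedFamily, query_id: str) -> AlignedFamily:
    """Remove alignment columns where the query sequence has a gap.

    Column order is preserved; the result has L' equal to the number of
    non-gap positions of the query.
    """
    qrow = family.rows[family.index_of(query_id)]
    keep = qrow != family.alphabet.gap_index
    return AlignedFamily(
        list(family.ids), family.rows[:, keep], family.alphabet, query_id
    )


def kept_columns(family: AlignedFamily, query_id: str) -> np.ndarray:
    """0-based indices of the columns that query-centric reduction retains."""
    qrow = family.rows[family.index_of(query_id)]
    return np.flatnonzero(qrow != family.alphabet.gap_index)


def density_reweight(family: AlignedFamily, identity_threshold: float = 0.8) -> SequenceWeights:
    """Weight each sequence by the inverse size of its identity neighborhood.

    w_i = 1 / |{ j : identity(i, j) >= threshold }|, the set including i
    itself, with fractional identity computed over columns where the pair is
    not gap-gap.  Sequences with no neighbor above threshold get weight 1.
    """
    if not (0.0 < identity_threshold < 1.0):
        raise ValueError("identity_threshold must lie in (0, 1)")
    rows = family.rows
    N = family.N
    gap = family.alphabet.gap_index
    is_gap = rows == gap
    counts = np.zeros(N, dtype=np.int64)
    for i in range(N):
        eq = rows == rows[i]  # (N, L)
        both_gap = is_gap & is_gap[i]
        denom = rows.shape[1] - both_gap.sum(axis=1)
        matches = (eq & ~both_gap).sum(axis=1)
        ident = np.where(denom > 0, matches / np.maximum(denom, 1), 1.0)
        counts[i] = int(np.sum(ident >= identity_threshold))
    return SequenceWeights(list(family.ids), 1.0 / counts, identity_threshold)
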