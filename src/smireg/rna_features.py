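"""miRNA sequence descriptors.

A mature miRNA sequence is encoded as a 277-dimensional numeric vector:

    [length (1)] ++ [mononucleotide ratios A,C,G,U (4)]
                 ++ [2-mer frequencies (16)] ++ [4-mer frequencies (256)]

k-mer frequency = overlapping-window count / (L - k + 1), so each k-block
is a probability vector.  k-mers are ordered lexicographically with
A < C < G < U; the ordering is frozen because trained models depend on it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

ALPHABET = "ACGU"
DESCRIPTOR_DIM = 277

_VALID_INPUT = set("ACGUTacgut")


def normalize_sequence(raw: str) -> str:
    """Uppercase, map T->U and validate a raw nucleotide string.

    Raises ``ValueError`` naming the first offending character and its
    1-based position; ambiguity codes (N, R, ...) are rejected, not skipped.
    """
    if not raw:
        raise ValueError("empty sequence")
    for pos, ch in enumerate(raw, start=1):
        if ch not in _VALID_INPUT:
            raise ValueError(
                f"invalid character {ch!r} at position {pos}: "
                "only A/C/G/U (or T) are accepted"
            )
    return raw.upper().replace("T", "U")


@dataclass(frozen=True)
class MiRNARecord:
    """An identified mature miRNA sequence over {A, C, G, U}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if len(self.sequence) < 4:
            raise ValueError(
                f"sequence for {self.id!r} has length {len(self.sequence)} < 4; "
                "4-mer frequencies are undefined"
            )


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order (A < C < G < U)."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def kmer_frequencies(seq: str, k: int) -> dict[str, float]:
    """Overlapping k-mer frequencies over all 4^k k-mers.

    Frequency of a k-mer is its overlapping-occurrence count divided by the
    number of windows (len(seq) - k + 1); absent k-mers map to 0.0 and the
    values sum to 1.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    counts: dict[str, int] = {}
    for i in range(n_windows):
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return {kmer: counts.get(kmer, 0) / n_windows for kmer in all_kmers(k)}


def descriptor_columns() -> list[str]:
    """Frozen column names for the 277 descriptor entries."""
    cols = ["len"] + [f"ratio_{b}" for b in ALPHABET]
    cols += [f"f_{m}" for m in all_kmers(2)]
    cols += [f"f_{m}" for m in all_kmers(4)]
    return cols


def build_descriptor(rec: MiRNARecord) -> np.ndarray:
    """277-dimensional descriptor: length, base ratios, 2-mer and 4-mer frequencies."""
    seq = rec.sequence
    parts = [np.array([float(len(seq))])]
    for k in (1, 2, 4):
        parts.append(np.fromiter(kmer_frequencies(seq, k).values(), dtype=float))
    vec = np.concatenate(parts)
    assert vec.shape == (DESCRIPTOR_DIM,)
    return vec


def read_fasta(path: str | Path) -> dict[str, MiRNARecord]:
    """Read miRNA records from FASTA; the header token up to whitespace is the id."""
    records: dict[str, MiRNARecord] = {}
    for sr in SeqIO.parse(str(path), "fasta"):
        records[sr.id] = MiRNARecord(id=sr.id, sequence=str(sr.seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[MiRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def descriptor_table(records: Iterable[MiRNARecord]) -> pd.DataFrame:
    """One row per miRNA, 277 named columns, indexed by miRNA id."""
    recs = list(records)
    mat = np.vstack([build_descriptor(r) for r in recs]) if recs else np.empty((0, DESCRIPTOR_DIM))
    return pd.DataFrame(mat, index=[r.id for r in recs], columns=descriptor_columns())


def export_descriptors(records: Iterable[MiRNARecord], path: str | Path) -> None:
    descriptor_table(records).to_csv(path, sep="\t", index_label="mirna_id")
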