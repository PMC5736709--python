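"""Multiple sequence alignments and FASTA input/output."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP_CHARS


@dataclass
class Alignment:
    """A protein multiple alignment over the 20-letter alphabet plus gaps.

    ``match_mask`` marks which columns are treated as match (consensus)
    columns when a profile HMM is built; it is filled in by the builder and
    may be ``None`` on a freshly loaded alignment.
    """

    records: list[tuple[str, str]]
    match_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must all have the same length")
        if self.n_columns < 1:
            raise ValueError("alignment has no columns")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.records)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return sum(c in GAP_CHARS for c in col) / len(col)

    def ungapped(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return "".join(c for c in seq if c not in GAP_CHARS)
        raise KeyError(rid)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: sample columns with replacement."""
        n = self.n_columns
        idx = rng.integers(0, n, size=n)
        recs = [(rid, "".join(seq[j] for j in idx)) for rid, seq in self.records]
        return Alignment(recs)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = set(ids)
        return Alignment([(r, s) for r, s in self.records if r in keep])


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs, rejecting duplicate ids."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no sequences parsed from {path}")
    return records


def read_alignment(path: str | Path) -> Alignment:
    return Alignment(read_fasta(path))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta")
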