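"""Sequence records, alignments and FASTA round-trip I/O.

Coordinates are 1-based inclusive in all in-memory reports; file formats that
are conventionally 0-based half-open (BED-like tables, the disjunct-site JSON
plan) convert explicitly at the file boundary and say so in their headers.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("trpscan")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: index layout used throughout: 0..19 residues, 20 gap, 21 ambiguous X
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_INDEX = 20
X_INDEX = 21

VALID_RECORD_SYMBOLS = set(AMINO_ACIDS) | {"X"}
VALID_ALIGNED_SYMBOLS = VALID_RECORD_SYMBOLS | {GAP}


class FormatError(ValueError):
    """Malformed sequence input (illegal symbol, ragged alignment, ...)."""


def validate_symbols(seq: str, allowed: set[str], context: str) -> None:
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in allowed]
    if bad:
        shown = ", ".join(f"{c!r}@{i}" for i, c in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise FormatError(f"{context}: illegal symbols {shown}{more}")


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus an amino-acid sequence (ungapped)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        validate_symbols(self.seq, VALID_RECORD_SYMBOLS, f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass
class Alignment:
    """Equal-length gapped rows over the 20 amino acids plus '-' and 'X'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("alignment: ids and rows differ in number")
        if not self.rows:
            raise FormatError("alignment: empty")
        width = len(self.rows[0])
        for name, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise FormatError(
                    f"alignment: row {name!r} has length {len(row)}, expected {width}"
                )
            validate_symbols(row, VALID_ALIGNED_SYMBOLS, f"aligned row {name!r}")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        """Column *j* (0-based) as a string, one character per row."""
        return "".join(row[j] for row in self.rows)

    def to_indices(self) -> np.ndarray:
        """(n_seqs, n_cols) uint8 matrix; 0..19 residues, 20 gap, 21 X."""
        lut = np.full(128, 255, dtype=np.uint8)
        for a, i in AA_INDEX.items():
            lut[ord(a)] = i
        lut[ord(GAP)] = GAP_INDEX
        lut[ord("X")] = X_INDEX
        raw = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return lut[raw].reshape(self.n_seqs, self.n_cols)

    def subset(self, indices: Sequence[int]) -> "Alignment":
        return Alignment([self.ids[i] for i in indices], [self.rows[i] for i in indices])

    def row_of(self, name: str) -> str:
        return self.rows[self.ids.index(name)]


def records_to_alignment(records: Iterable[ProteinRecord]) -> Alignment:
    """Treat equal-length ungapped records as a column-addressable alignment."""
    recs = list(records)
    return Alignment([r.id for r in recs], [r.seq for r in recs])


def _normalise(name: str, seq: str) -> str:
    if any(c.islower() for c in seq):
        log.info("record %s: lowercase symbols normalised to uppercase", name)
        seq = seq.upper()
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise(rec.id, str(rec.seq))
        validate_symbols(seq, VALID_RECORD_SYMBOLS, f"record {rec.id!r} in {path}")
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
            fh,
            "fasta",
        )


def read_alignment(path: str | Path) -> Alignment:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalise(rec.id, str(rec.seq)))
    return Alignment(ids, rows)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(
            (
                SeqRecord(Seq(row), id=name, description="")
                for name, row in zip(alignment.ids, alignment.rows)
            ),
            fh,
            "fasta",
        )
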