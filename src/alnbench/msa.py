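"""Gapped multiple alignments over DNA, with multi-FASTA I/O.

Rows are ordered and named; the gap character is ``-``.  Columns that are
entirely gaps are rejected by the constructor (use ``drop_empty_columns``
first when importing simulator output, which keeps a column per residue ever
created).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
ALPHABET = set("ACGTN-")

__all__ = ["GAP", "MultipleAlignment", "read_fasta", "write_fasta"]


@dataclass(frozen=True)
class MultipleAlignment:
    """An ordered, named set of equal-length gapped rows."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate row names")
        if not self.rows:
            raise ValueError("empty alignment")
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise ValueError("rows differ in length")
        bad = set("".join(self.rows)) - ALPHABET
        if bad:
            raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")
        for j in range(length):
            if all(r[j] == GAP for r in self.rows):
                raise ValueError(f"column {j} is entirely gaps")

    @classmethod
    def from_mapping(cls, rows: Mapping[str, str]) -> "MultipleAlignment":
        return cls(tuple(rows.keys()), tuple(str(v).upper() for v in rows.values()))

    @classmethod
    def from_rows(
        cls, names: Iterable[str], rows: Iterable[str], drop_empty: bool = False
    ) -> "MultipleAlignment":
        names = tuple(names)
        rows = tuple(str(r).upper() for r in rows)
        if drop_empty and rows:
            keep = [j for j in range(len(rows[0])) if any(r[j] != GAP for r in rows)]
            rows = tuple("".join(r[j] for j in keep) for r in rows)
        return cls(names, rows)

    def __len__(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no row named {name!r}") from None

    def ungapped(self, name: str) -> str:
        return self.row(name).replace(GAP, "")

    def sequences(self) -> dict[str, str]:
        return {name: self.ungapped(name) for name in self.names}

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(r[j] for r in self.rows)

    def reordered(self, names: Iterable[str]) -> "MultipleAlignment":
        names = tuple(names)
        return MultipleAlignment(names, tuple(self.row(n) for n in names))

    def reversed_columns(self) -> "MultipleAlignment":
        return MultipleAlignment(self.names, tuple(r[::-1] for r in self.rows))

    def to_fasta(self) -> str:
        buf = io.StringIO()
        records = [
            SeqRecord(Seq(row), id=name, description="")
            for name, row in zip(self.names, self.rows)
        ]
        SeqIO.write(records, buf, "fasta")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())

    @classmethod
    def read(cls, path, drop_empty: bool = False) -> "MultipleAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_rows(
            (r.id for r in records), (str(r.seq) for r in records), drop_empty=drop_empty
        )


def read_fasta(path) -> dict[str, str]:
    """Read ungapped sequences from a FASTA file, uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    seqs = {r.id: str(r.seq).upper() for r in records}
    if len(seqs) != len(records):
        raise ValueError(f"duplicate sequence names in {path}")
    return seqs


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
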