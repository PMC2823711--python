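"""Conserved-block detection from per-column conservation scores.

A block is a maximal run of at least ``min_run`` consecutive columns that are
all non-gapped (no gap in any row) and all score at or above ``min_score``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import GAP, MultipleAlignment

__all__ = [
    "ScoredColumns",
    "find_conserved_blocks",
    "block_fraction",
    "read_score_track",
    "write_blocks",
    "project_to_row",
]


@dataclass(frozen=True)
class ScoredColumns:
    """Per-column conservation scores plus a per-column any-gap flag."""

    scores: np.ndarray
    gapped: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        gapped = np.asarray(self.gapped, dtype=bool)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "gapped", gapped)
        if scores.ndim != 1 or gapped.shape != scores.shape:
            raise ValueError("scores and gap flags must be 1-d and equal length")
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError("scores must lie in [0,1]")

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def from_alignment(cls, alignment: MultipleAlignment, scores) -> "ScoredColumns":
        scores = np.asarray(scores, dtype=float)
        if len(scores) != len(alignment):
            raise ValueError("score track length differs from alignment length")
        gapped = np.array(
            [any(r[j] == GAP for r in alignment.rows) for j in range(len(alignment))]
        )
        return cls(scores, gapped)


def find_conserved_blocks(
    columns: ScoredColumns, min_run: int = 10, min_score: float = 0.9
) -> list[tuple[int, int]]:
    """Maximal half-open runs of non-gapped columns scoring >= ``min_score``,
    kept when at least ``min_run`` columns long."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    ok = (~columns.gapped) & (columns.scores >= min_score)
    blocks: list[tuple[int, int]] = []
    start = None
    for j, good in enumerate(ok):
        if good and start is None:
            start = j
        elif not good and start is not None:
            if j - start >= min_run:
                blocks.append((start, j))
            start = None
    if start is not None and len(ok) - start >= min_run:
        blocks.append((start, len(ok)))
    return blocks


def block_fraction(blocks, alignment_length: int) -> float:
    """Total block columns / alignment length."""
    if alignment_length < 1:
        raise ValueError("alignment_length must be >= 1")
    prev_end = 0
    total = 0
    for start, end in sorted(blocks):
        if start < prev_end:
            raise ValueError(f"overlapping intervals at [{start},{end})")
        if not (0 <= start < end <= alignment_length):
            raise ValueError(f"interval [{start},{end}) out of bounds")
        total += end - start
        prev_end = end
    return total / alignment_length


def project_to_row(
    blocks, alignment: MultipleAlignment, reference: str
) -> list[tuple[int, int]]:
    """Map alignment-column intervals to ungapped coordinates of one row.

    Columns where the reference row is gapped contribute no positions; empty
    projections are dropped.
    """
    row = alignment.row(reference)
    # ungapped position at or after each column
    positions = []
    pos = 0
    for ch in row:
        positions.append(pos)
        if ch != GAP:
            pos += 1
    positions.append(pos)
    out = []
    for start, end in blocks:
        lo, hi = positions[start], positions[end]
        if hi > lo:
            out.append((lo, hi))
    return out


def read_score_track(path, length: int | None = None) -> np.ndarray:
    """Read a per-column score track: TSV rows of (column, score) or bare scores."""
    cols: dict[int, float] = {}
    bare: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 1:
                    bare.append(float(fields[0]))
                else:
                    cols[int(fields[0])] = float(fields[1])
            except ValueError:
                raise ValueError(f"{path}: bad score row {lineno}") from None
    if bare and cols:
        raise ValueError(f"{path}: mixed bare and indexed score rows")
    if bare:
        return np.asarray(bare)
    n = length if length is not None else (max(cols) + 1 if cols else 0)
    track = np.zeros(n)
    for j, s in cols.items():
        if j >= n:
            raise ValueError(f"{path}: column {j} beyond track length {n}")
        track[j] = s
    return track


def write_blocks(path, blocks, name: str = "block") -> None:
    """BED-like TSV of half-open intervals."""
    with open(path, "w") as fh:
        for k, (start, end) in enumerate(blocks):
            fh.write(f"{name}\t{start}\t{end}\t{name}_{k}\n")
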