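"""Heads-or-tails (HoT) alignment reliability scoring, with a deterministic
built-in progressive aligner so no external binary is required.

The HoT protocol aligns the original sequences ("heads") and their reversed
versions ("tails", re-reversed afterwards so both alignments cover the
original sequences), then scores the agreement between the two:

* SPS — pooled residue–residue pair agreement over all unordered row pairs;
* CS  — identical-column agreement (columns compared as full residue-index/
  gap assignments).

Both scores are on a 0–100 scale; the denominator is the mean of the heads
and tails pool sizes by default (``denominator="heads"`` for heads-only).

The built-in aligner is a progressive profile–profile global aligner with
affine gaps (match +5, mismatch −4, gap open −10, gap extend −0.5 per gapped
position), guided by a supplied phylogeny or by UPGMA on k-mer distances.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
from scipy.cluster.hierarchy import linkage

from .eval_metrics import GAP_PARTNER, partner_labels
from .msa import GAP, MultipleAlignment, read_fasta, write_fasta
from .phylo import Phylogeny, TreeNode

__all__ = [
    "MATCH",
    "MISMATCH",
    "GAP_OPEN",
    "GAP_EXTEND",
    "HomologyPairSet",
    "HotScores",
    "progressive_align",
    "pairwise_score",
    "homology_pairs",
    "hot_sps",
    "hot_cs",
    "hot_pipeline",
    "reverse_sequences",
    "CommandLineAligner",
]

MATCH = 5.0
MISMATCH = -4.0
GAP_OPEN = -10.0      # charged once per gap run
GAP_EXTEND = -0.5     # charged per gapped position

_CHAR_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# N scores 0 against everything
_SUBST = np.full((5, 5), MISMATCH)
np.fill_diagonal(_SUBST, MATCH)
_SUBST[4, :] = 0.0
_SUBST[:, 4] = 0.0

_NEG_INF = -1e30


def _profile_counts(rows: tuple[str, ...]) -> np.ndarray:
    """Per-column counts over {A,C,G,T,N}; gaps contribute nothing."""
    length = len(rows[0])
    counts = np.zeros((length, 5))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                counts[j, _CHAR_INDEX[ch]] += 1
    return counts


def _align_profiles(
    x_rows: tuple[str, ...], y_rows: tuple[str, ...]
) -> tuple[tuple[str, ...], tuple[str, ...], float]:
    """Global affine-gap alignment of two profiles (Gotoh, rows vectorized).

    Returns the gapped x rows, gapped y rows, and the optimal score.
    """
    lx, ly = len(x_rows[0]), len(y_rows[0])
    cx = _profile_counts(x_rows)
    cy = _profile_counts(y_rows)
    # column-vs-column score, averaged over row pairs (gap rows contribute 0)
    sub = (cx @ _SUBST @ cy.T) / (len(x_rows) * len(y_rows))

    j_idx = np.arange(ly + 1)
    B = np.empty((lx + 1, ly + 1))
    E = np.full((lx + 1, ly + 1), _NEG_INF)
    F = np.full((lx + 1, ly + 1), _NEG_INF)
    B[0, 0] = 0.0
    B[0, 1:] = GAP_OPEN + GAP_EXTEND * j_idx[1:]
    E[0, 1:] = B[0, 1:]
    for i in range(1, lx + 1):
        B[i, 0] = F[i, 0] = GAP_OPEN + GAP_EXTEND * i
        diag = B[i - 1, :ly] + sub[i - 1, :]
        F[i, 1:] = np.maximum(F[i - 1, 1:], B[i - 1, 1:] + GAP_OPEN) + GAP_EXTEND
        c = np.empty(ly + 1)
        c[0] = B[i, 0]
        c[1:] = np.maximum(diag, F[i, 1:])
        run = np.maximum.accumulate(c + GAP_OPEN - GAP_EXTEND * j_idx)
        E[i, 1:] = GAP_EXTEND * j_idx[1:] + run[:-1]
        B[i, 1:] = np.maximum(c[1:], E[i, 1:])

    # traceback: ops are 'D' (column from both), 'X' (x column vs gap),
    # 'Y' (y column vs gap), collected end-to-start.  Equality checks use a
    # tolerance because profile column scores are averaged counts.
    eps = 1e-6
    ops: list[str] = []
    i, j = lx, ly
    state = "B"
    while i > 0 or j > 0:
        if state == "B":
            if i == 0:
                ops.append("Y")
                j -= 1
            elif j == 0:
                ops.append("X")
                i -= 1
            elif abs(B[i, j] - (B[i - 1, j - 1] + sub[i - 1, j - 1])) < eps:
                ops.append("D")
                i -= 1
                j -= 1
            elif abs(B[i, j] - F[i, j]) < eps:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("X")
            if i - 1 == 0 or abs(
                B[i - 1, j] + GAP_OPEN + GAP_EXTEND - F[i, j]
            ) < eps:
                state = "B"
            i -= 1
            # else stay in F (continue the vertical gap)
        else:  # E
            ops.append("Y")
            if j - 1 == 0:
                j -= 1
                state = "B"
            else:
                prev_c = max(B[i - 1, j - 2] + sub[i - 1, j - 2], F[i, j - 1])
                if abs(prev_c + GAP_OPEN + GAP_EXTEND - E[i, j]) < eps:
                    # exit the horizontal gap into the max(diag, F) source
                    j -= 1
                    if B[i - 1, j - 1] + sub[i - 1, j - 1] >= F[i, j]:
                        ops.append("D")
                        i -= 1
                        j -= 1
                        state = "B"
                    else:
                        state = "F"
                else:
                    j -= 1  # continue the horizontal gap
    ops.reverse()

    # 'D' consumes both; 'X' consumes x only; 'Y' consumes y only
    def _expand_x(rows):
        out = []
        for row in rows:
            chars, pos = [], 0
            for op in ops:
                if op in ("D", "X"):
                    chars.append(row[pos])
                    pos += 1
                else:
                    chars.append(GAP)
            out.append("".join(chars))
        return tuple(out)

    def _expand_y(rows):
        out = []
        for row in rows:
            chars, pos = [], 0
            for op in ops:
                if op in ("D", "Y"):
                    chars.append(row[pos])
                    pos += 1
                else:
                    chars.append(GAP)
            out.append("".join(chars))
        return tuple(out)

    return _expand_x(x_rows), _expand_y(y_rows), float(B[lx, ly])


def pairwise_score(seq_a: str, seq_b: str) -> float:
    """Optimal global affine-gap alignment score of two sequences."""
    _, _, score = _align_profiles((seq_a.upper(),), (seq_b.upper(),))
    return score


def _kmer_distance(a: str, b: str, k: int) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / len(ka | kb)


def _guide_from_kmers(names: list[str], seqs: Mapping[str, str]) -> TreeNode:
    """UPGMA (average linkage) merge tree on k-mer Jaccard distances."""
    if len(names) == 1:
        return TreeNode(name=names[0])
    k = max(1, min(6, min(len(seqs[n]) for n in names) // 2))
    condensed = [
        _kmer_distance(seqs[a], seqs[b], k) for a, b in combinations(names, 2)
    ]
    merge = linkage(np.asarray(condensed), method="average")
    nodes: list[TreeNode] = [TreeNode(name=n) for n in names]
    for left, right, _, _ in merge:
        nodes.append(TreeNode(children=[nodes[int(left)], nodes[int(right)]]))
    return nodes[-1]


def progressive_align(
    sequences: Mapping[str, str], guide: Phylogeny | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment ("once a gap, always a gap").

    Pairwise/profile merges follow the guide tree when given (it must cover
    at least the input names; extra leaves are pruned), else a UPGMA tree on
    k-mer distances.
    """
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = [(name, seq) for name, seq in sequences]
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names")
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = {}
    for name, raw in items:
        seq = str(raw).upper()
        if not seq:
            raise ValueError(f"empty sequence {name!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"unexpected characters in {name!r}: {sorted(bad)}")
        seqs[name] = seq

    if guide is not None:
        guide_names = set(guide.leaf_names())
        if not set(names) <= guide_names:
            raise ValueError("guide tree is missing some sequence names")
        root = (
            guide.prune_to(names).root if guide_names != set(names) else guide.root
        )
    else:
        root = _guide_from_kmers(names, seqs)

    def _align(node: TreeNode) -> tuple[tuple[str, ...], tuple[str, ...]]:
        if node.is_leaf:
            return (node.name,), (seqs[node.name],)
        sub_names, sub_rows = _align(node.children[0])
        for child in node.children[1:]:
            other_names, other_rows = _align(child)
            sub_rows, other_rows, _ = _align_profiles(sub_rows, other_rows)
            sub_names = sub_names + other_names
            sub_rows = sub_rows + other_rows
        return sub_names, sub_rows

    out_names, out_rows = _align(root)
    aln = MultipleAlignment.from_rows(out_names, out_rows, drop_empty=True)
    return aln.reordered(names)


# ---------------------------------------------------------------------------
# HoT scores

@dataclass(frozen=True)
class HomologyPairSet:
    """Co-columned residue pairs for one unordered row pair, plus per-residue
    partner labels (partner residue index, or -1 for a gap partner)."""

    name_i: str
    name_j: str
    pairs: frozenset[tuple[int, int]]
    partners_i: tuple[int, ...]
    partners_j: tuple[int, ...]


def homology_pairs(
    alignment: MultipleAlignment, name_i: str, name_j: str
) -> HomologyPairSet:
    partners_i, partners_j = partner_labels(alignment, name_i, name_j)
    pairs = frozenset(
        (p, q) for p, q in enumerate(partners_i) if q != GAP_PARTNER
    )
    return HomologyPairSet(
        name_i, name_j, pairs, tuple(partners_i), tuple(partners_j)
    )


def _check_same_sequences(a: MultipleAlignment, b: MultipleAlignment) -> None:
    if set(a.names) != set(b.names):
        raise ValueError("alignments cover different sequences")
    for name in a.names:
        if a.ungapped(name) != b.ungapped(name):
            raise ValueError(f"ungapped sequence mismatch for {name!r}")


def _pair_pool(alignment: MultipleAlignment) -> set[tuple]:
    pool: set[tuple] = set()
    for name_i, name_j in combinations(sorted(alignment.names), 2):
        hp = homology_pairs(alignment, name_i, name_j)
        pool.update((name_i, name_j, p, q) for p, q in hp.pairs)
    return pool


def _normalized(shared: int, size_a: int, size_b: int, denominator: str) -> float:
    if denominator == "mean":
        denom = (size_a + size_b) / 2.0
    elif denominator == "heads":
        denom = float(size_a)
    else:
        raise ValueError("denominator must be 'mean' or 'heads'")
    if denom == 0:
        return 100.0
    return 100.0 * shared / denom


def hot_sps(
    aln_heads: MultipleAlignment,
    aln_tails: MultipleAlignment,
    denominator: str = "mean",
) -> float:
    """Pooled residue-pair agreement between the two alignments, in [0,100]."""
    _check_same_sequences(aln_heads, aln_tails)
    pool_h = _pair_pool(aln_heads)
    pool_t = _pair_pool(aln_tails)
    return _normalized(len(pool_h & pool_t), len(pool_h), len(pool_t), denominator)


def _column_set(alignment: MultipleAlignment) -> set[tuple]:
    names = sorted(alignment.names)
    rows = [alignment.row(n) for n in names]
    positions = [0] * len(rows)
    columns: set[tuple] = set()
    for j in range(len(alignment)):
        signature = []
        for r, row in enumerate(rows):
            if row[j] == GAP:
                signature.append(GAP_PARTNER)
            else:
                signature.append(positions[r])
                positions[r] += 1
        columns.add(tuple(signature))
    return columns


def hot_cs(
    aln_heads: MultipleAlignment,
    aln_tails: MultipleAlignment,
    denominator: str = "mean",
) -> float:
    """Identical-column agreement between the two alignments, in [0,100]."""
    _check_same_sequences(aln_heads, aln_tails)
    cols_h = _column_set(aln_heads)
    cols_t = _column_set(aln_tails)
    return _normalized(len(cols_h & cols_t), len(cols_h), len(cols_t), denominator)


@dataclass(frozen=True)
class HotScores:
    sps: float
    cs: float


def reverse_sequences(sequences: Mapping[str, str]) -> dict[str, str]:
    return {name: seq[::-1] for name, seq in sequences.items()}


def hot_pipeline(
    sequences: Mapping[str, str],
    aligner: Callable[[Mapping[str, str]], MultipleAlignment] | None = None,
    guide: Phylogeny | None = None,
    denominator: str = "mean",
) -> HotScores:
    """Compute (SPS, CS) between the heads and re-reversed tails alignments."""
    if aligner is None:
        aligner = lambda s: progressive_align(s, guide=guide)  # noqa: E731
    heads = aligner(sequences)
    tails_rev = aligner(reverse_sequences(sequences))
    tails = tails_rev.reversed_columns()
    return HotScores(
        sps=hot_sps(heads, tails, denominator=denominator),
        cs=hot_cs(heads, tails, denominator=denominator),
    )


# ---------------------------------------------------------------------------
# External-aligner adapter

class CommandLineAligner:
    """Adapter around an external aligner invoked as a command template.

    The template must contain ``{input}`` and ``{output}`` placeholders for
    FASTA paths, e.g. ``"mafft --quiet {input} > {output}"``.  The returned
    alignment is validated to preserve sequence content and re-ordered to the
    input name order.
    """

    def __init__(self, template: str, timeout: float = 600.0):
        if "{input}" not in template or "{output}" not in template:
            raise ValueError("template must contain {input} and {output}")
        self.template = template
        self.timeout = timeout

    def __call__(self, sequences: Mapping[str, str]) -> MultipleAlignment:
        with tempfile.TemporaryDirectory() as tmp:
            in_path = Path(tmp) / "in.fasta"
            out_path = Path(tmp) / "out.fasta"
            write_fasta(in_path, sequences)
            cmd = self.template.format(input=in_path, output=out_path)
            try:
                subprocess.run(
                    cmd, shell=True, check=True, timeout=self.timeout,
                    capture_output=True,
                )
            except subprocess.CalledProcessError as exc:
                raise RuntimeError(
                    f"aligner command failed ({exc.returncode}): {cmd}\n"
                    f"{exc.stderr.decode(errors='replace')}"
                ) from exc
            aln = MultipleAlignment.read(out_path, drop_empty=True)
        if set(aln.names) != set(sequences):
            raise ValueError("aligner returned different sequence names")
        for name, seq in sequences.items():
            if aln.ungapped(name) != seq.upper():
                raise ValueError(f"aligner altered sequence content of {name!r}")
        return aln.reordered(list(sequences))
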