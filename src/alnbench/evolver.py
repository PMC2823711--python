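"""Sequence evolution along a phylogeny: F81 substitutions, geometric-mixture
indels, and conserved-block rate heterogeneity.

The simulator is an exact Gillespie process per branch.  Per-site event rates:

* substitution: ``m * (1 - pi[b]) / (1 - sum(pi**2))`` for a site with rate
  multiplier ``m`` currently holding base ``b`` (F81 jump chain; the
  normalisation makes branch length equal expected substitutions per neutral
  site).  With uniform base frequencies this is exactly ``m``.
* indel initiation: ``m / rho`` (or ``1 / rho`` when block scaling of indel
  rates is disabled), split into an insertion fraction ``r/(1+r)`` and a
  deletion fraction ``1/(1+r)``.

Insertions place i.i.d. bases immediately left of the anchor site; a virtual
terminal anchor (multiplier 1) permits 3'-end insertions.  Deletions extend
rightward and are truncated at the sequence end.  Every residue ever created
owns one column of the true alignment, kept in a global doubly-linked column
list so that insertions on independent lineages interleave consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .msa import GAP, MultipleAlignment
from .phylo import Phylogeny

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "BlockMap",
    "IndelLengthModel",
    "FixedLength",
    "GeometricLength",
    "EmpiricalLength",
    "EvolutionParams",
    "Event",
    "SimulatedDataset",
    "place_conserved_blocks",
    "sample_indel_length",
    "evolve_branch",
    "simulate_dataset",
    "write_event_log",
    "read_event_log",
]


# ---------------------------------------------------------------------------
# Length distributions

@dataclass(frozen=True)
class IndelLengthModel:
    """Mixture of two geometric distributions on {1, 2, ...}."""

    weight: float = 0.7
    q1: float = 0.4
    q2: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"mixture weight must be in [0,1], got {self.weight}")
        for q in (self.q1, self.q2):
            if not 0.0 < q <= 1.0:
                raise ValueError(f"geometric parameter must be in (0,1], got {q}")

    @property
    def mean(self) -> float:
        return self.weight / self.q1 + (1.0 - self.weight) / self.q2

    def pmf(self, k: int) -> float:
        if k < 1:
            return 0.0
        return self.weight * self.q1 * (1 - self.q1) ** (k - 1) + (
            1 - self.weight
        ) * self.q2 * (1 - self.q2) ** (k - 1)

    def sample(self, rng: np.random.Generator) -> int:
        q = self.q1 if rng.random() < self.weight else self.q2
        return int(rng.geometric(q))


def sample_indel_length(model: IndelLengthModel, rng: np.random.Generator) -> int:
    """Draw an indel length from the two-geometric mixture (support >= 1)."""
    return model.sample(rng)


@dataclass(frozen=True)
class FixedLength:
    """Degenerate length distribution (every draw equals ``value``)."""

    value: int

    @property
    def mean(self) -> float:
        return float(self.value)

    def sample(self, rng: np.random.Generator) -> int:
        return int(self.value)


@dataclass(frozen=True)
class GeometricLength:
    """Geometric length distribution on {1, 2, ...} with the given mean."""

    mean_length: float = 50.0

    def __post_init__(self):
        if not self.mean_length >= 1.0:
            raise ValueError("mean_length must be >= 1")

    @property
    def mean(self) -> float:
        return float(self.mean_length)

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.geometric(1.0 / self.mean_length))


@dataclass(frozen=True)
class EmpiricalLength:
    """Uniform draw from a list of observed lengths."""

    lengths: tuple[int, ...]

    def __post_init__(self):
        if not self.lengths or any(l < 1 for l in self.lengths):
            raise ValueError("need at least one length, all >= 1")

    @property
    def mean(self) -> float:
        return float(np.mean(self.lengths))

    def sample(self, rng: np.random.Generator) -> int:
        return int(self.lengths[rng.integers(len(self.lengths))])


# ---------------------------------------------------------------------------
# Conserved blocks

@dataclass(frozen=True)
class BlockMap:
    """Non-overlapping half-open intervals with reduced rate multipliers.

    Sites outside every interval have implicit multiplier 1.
    """

    length: int
    intervals: tuple[tuple[int, int], ...] = ()
    multipliers: tuple[float, ...] = ()

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if len(self.intervals) != len(self.multipliers):
            raise ValueError("intervals and multipliers differ in count")
        prev_end = 0
        for (start, end), mult in zip(self.intervals, self.multipliers):
            if not (0 <= start < end <= self.length):
                raise ValueError(f"interval [{start},{end}) out of bounds")
            if start < prev_end:
                raise ValueError("intervals overlap or are unsorted")
            if not 0.0 < mult <= 1.0:
                raise ValueError(f"multiplier must be in (0,1], got {mult}")
            prev_end = end

    def coverage(self) -> float:
        if self.length == 0:
            return 0.0
        return sum(e - s for s, e in self.intervals) / self.length

    def site_multipliers(self) -> np.ndarray:
        mults = np.ones(self.length)
        for (start, end), m in zip(self.intervals, self.multipliers):
            mults[start:end] = m
        return mults


def place_conserved_blocks(
    root_length: int,
    alpha: float,
    block_length_dist,
    rng: np.random.Generator,
    beta: float = 0.1,
) -> BlockMap:
    """Lay out alternating spacers and conserved blocks over a root sequence.

    Spacer lengths are geometric with mean ``mu_b * (1 - alpha) / alpha``
    (``mu_b`` = mean block length), so asymptotic expected coverage is
    ``alpha``.  The scan starts with a block with probability ``alpha``
    (approximate stationary start) to avoid finite-length undershoot.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0,1), got {alpha}")
    if root_length < 0:
        raise ValueError("root_length must be >= 0")
    if alpha == 0.0 or root_length == 0:
        return BlockMap(root_length)

    mu_b = float(block_length_dist.mean)
    if mu_b < 1.0:
        raise ValueError("mean block length must be >= 1")
    p_spacer = min(1.0, alpha / (mu_b * (1.0 - alpha)))

    intervals: list[tuple[int, int]] = []
    pos = 0
    in_block = bool(rng.random() < alpha)
    while pos < root_length:
        if in_block:
            length = int(block_length_dist.sample(rng))
            if length < 1:
                raise ValueError("block length distribution produced a length < 1")
            end = min(pos + length, root_length)
            intervals.append((pos, end))
            pos = end
        else:
            pos += int(rng.geometric(p_spacer))
        in_block = not in_block
    return BlockMap(root_length, tuple(intervals), (beta,) * len(intervals))


# ---------------------------------------------------------------------------
# Parameters

@dataclass(frozen=True)
class EvolutionParams:
    """Complete parameterization of one simulated data set."""

    tree: Phylogeny
    sub_indel_ratio: float = 10.0      # rho; math.inf disables indels
    ins_del_ratio: float = 1.0         # r
    indel_model: IndelLengthModel = field(default_factory=IndelLengthModel)
    alpha: float = 0.2
    beta: float = 0.1
    root_length: int = 10_000
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    block_length_dist: object = None   # defaults to EmpiricalLength fixture
    scale_indel_rates: bool = True     # blocks also suppress indels
    insert_rate_policy: str = "left"   # "left" | "neutral"
    seed: int | None = None

    def __post_init__(self):
        if not self.sub_indel_ratio > 0:
            raise ValueError("sub_indel_ratio must be > 0")
        if not self.ins_del_ratio > 0:
            raise ValueError("ins_del_ratio must be > 0")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0,1)")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0,1]")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be 4 positive values summing to 1")
        if self.insert_rate_policy not in ("left", "neutral"):
            raise ValueError("insert_rate_policy must be 'left' or 'neutral'")


# ---------------------------------------------------------------------------
# Events and columns

class _Col:
    """One true-alignment column; a node in the global doubly-linked list."""

    __slots__ = ("prev", "next")

    def __init__(self):
        self.prev: "_Col | None" = None
        self.next: "_Col | None" = None


@dataclass
class Event:
    branch_id: str
    kind: str                 # "substitution" | "insertion" | "deletion"
    time: float               # offset along the branch
    position: int             # 0-based, in the evolving sequence at event time
    length: int               # realized length (1 for substitutions)
    inserted_bases: str = ""
    columns: tuple = ()       # _Col refs during simulation; ints after resolve
    aln_col_start: int = -1
    aln_col_end: int = -1


@dataclass
class _BranchState:
    """Evolving sequence on one lineage: parallel column/base/multiplier lists."""

    cols: list
    bases: list
    mults: list

    def copy(self) -> "_BranchState":
        return _BranchState(list(self.cols), list(self.bases), list(self.mults))

    def text(self) -> str:
        return "".join(BASES[b] for b in self.bases)


class _ColumnUniverse:
    """Doubly-linked global ordering of every column ever created."""

    def __init__(self):
        self.head = _Col()
        self.tail = _Col()
        self.head.next = self.tail
        self.tail.prev = self.head
        self.count = 0

    def append(self) -> _Col:
        return self.insert_before(self.tail)

    def insert_before(self, anchor: _Col) -> _Col:
        col = _Col()
        col.prev = anchor.prev
        col.next = anchor
        anchor.prev.next = col
        anchor.prev = col
        self.count += 1
        return col

    def insert_after(self, anchor: _Col) -> _Col:
        return self.insert_before(anchor.next)

    def ordered(self) -> list[_Col]:
        out = []
        col = self.head.next
        while col is not self.tail:
            out.append(col)
            col = col.next
        return out


# ---------------------------------------------------------------------------
# Branch evolution (Gillespie)

def _f81_norm(pi: np.ndarray) -> float:
    return 1.0 / (1.0 - float(pi @ pi))


def evolve_branch(
    state: _BranchState,
    branch_length: float,
    params: EvolutionParams,
    rng: np.random.Generator,
    branch_id: str = "branch",
    universe: _ColumnUniverse | None = None,
) -> tuple[_BranchState, list[Event]]:
    """Evolve one lineage for ``branch_length`` expected substitutions/site.

    Returns the child state and the ordered event list.  ``universe`` is the
    shared column ordering; a private one is created when omitted (standalone
    use).
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if universe is None:
        universe = _ColumnUniverse()
    child = state.copy()
    events: list[Event] = []
    if branch_length == 0.0 or not child.bases:
        return child, events

    pi = np.asarray(params.pi, dtype=float)
    norm = _f81_norm(pi)
    base_leave = (1.0 - pi) * norm          # per-base leave factor
    max_leave = float(base_leave.max())
    rho = params.sub_indel_ratio
    has_indels = math.isfinite(rho)
    r = params.ins_del_ratio
    p_ins = r / (1.0 + r)
    anchor_rate = (1.0 / rho) * p_ins if has_indels else 0.0
    # F81 jump chain lookup: for each current base, the three candidate bases
    # and their cumulative probabilities (proportional to pi)
    jump_bases = np.empty((4, 3), dtype=np.intp)
    jump_cum = np.empty((4, 3))
    for old in range(4):
        others = [b for b in range(4) if b != old]
        weights = pi[others]
        jump_bases[old] = others
        jump_cum[old] = np.cumsum(weights / weights.sum())
    pi_cum = np.cumsum(pi)

    # Exact Gillespie via thinning: per-site rates are bounded above using the
    # largest leave factor, events are accepted with probability actual/bound.
    # Substitutions never change the bounds, so the cumulative-rate cache is
    # rebuilt only after indels (and the thinning is rejection-free under
    # uniform base frequencies).
    bound = None
    indel_rate = None
    cum = None
    total = 0.0

    def rebuild():
        nonlocal bound, indel_rate, cum, total
        mults = np.asarray(child.mults)
        if has_indels:
            indel_rate = (
                mults if params.scale_indel_rates else np.ones_like(mults)
            ) / rho
        else:
            indel_rate = np.zeros_like(mults)
        bound = mults * max_leave + indel_rate
        cum = np.cumsum(bound)
        total = float(cum[-1]) + anchor_rate

    rebuild()
    t = 0.0
    while True:
        t += rng.exponential(1.0 / total)
        if t >= branch_length:
            break
        u = rng.random() * total
        if u >= cum[-1]:
            site = len(child.bases)          # virtual terminal anchor: insertion
            is_sub = False
            is_ins = True
        else:
            site = int(np.searchsorted(cum, u, side="right"))
            sub_rate = child.mults[site] * base_leave[child.bases[site]]
            offset = u - (cum[site - 1] if site else 0.0)
            if offset < sub_rate:
                is_sub = True
            elif offset < sub_rate + indel_rate[site]:
                is_sub = False
                is_ins = None
            else:
                continue                     # thinning rejection: null event
        if u < cum[-1] and is_sub:
            old = child.bases[site]
            pick = int(np.searchsorted(jump_cum[old], rng.random(), side="right"))
            child.bases[site] = int(jump_bases[old, min(pick, 2)])
            events.append(
                Event(branch_id, "substitution", t, site, 1, columns=(child.cols[site],))
            )
            continue

        if is_ins is None:
            is_ins = rng.random() < p_ins
        length = sample_indel_length(params.indel_model, rng)
        if is_ins:
            bases = [
                int(np.searchsorted(pi_cum, x, side="right"))
                for x in np.minimum(rng.random(length), 1.0 - 1e-12)
            ]
            if params.insert_rate_policy == "neutral" or site == 0:
                mult = 1.0
            else:
                mult = child.mults[site - 1]
            n = len(child.bases)
            new_cols = []
            if site < n:
                anchor = child.cols[site]
                for _ in range(length):
                    new_cols.append(universe.insert_before(anchor))
            elif n > 0:
                after = child.cols[n - 1]
                for _ in range(length):
                    after = universe.insert_after(after)
                    new_cols.append(after)
            else:
                for _ in range(length):
                    new_cols.append(universe.append())
            child.cols[site:site] = new_cols
            child.bases[site:site] = bases
            child.mults[site:site] = [mult] * length
            events.append(
                Event(
                    branch_id,
                    "insertion",
                    t,
                    site,
                    length,
                    inserted_bases="".join(BASES[b] for b in bases),
                    columns=tuple(new_cols),
                )
            )
        else:
            end = min(site + length, len(child.bases))
            realized = end - site
            removed = tuple(child.cols[site:end])
            del child.cols[site:end]
            del child.bases[site:end]
            del child.mults[site:end]
            events.append(
                Event(branch_id, "deletion", t, site, realized, columns=removed)
            )
            if not child.bases:
                break
        rebuild()
    return child, events


# ---------------------------------------------------------------------------
# Whole-dataset simulation

@dataclass
class SimulatedDataset:
    """Leaf sequences, true alignment, event log, and the generating draw."""

    params: EvolutionParams
    root_sequence: str
    block_map: BlockMap
    leaf_sequences: dict[str, str]
    alignment_rows: dict[str, str]   # full column universe; may hold all-gap columns
    events: list[Event]

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.alignment_rows.values())))

    def to_msa(self, drop_empty: bool = True) -> MultipleAlignment:
        return MultipleAlignment.from_rows(
            self.alignment_rows.keys(), self.alignment_rows.values(), drop_empty=drop_empty
        )

    def event_counts(self) -> dict[str, int]:
        counts = {"substitution": 0, "insertion": 0, "deletion": 0}
        for event in self.events:
            counts[event.kind] += 1
        return counts


def _draw_root(params: EvolutionParams, root_pool, rng: np.random.Generator) -> str:
    n = params.root_length
    if root_pool is None:
        pi = np.asarray(params.pi, dtype=float)
        return "".join(BASES[i] for i in rng.choice(4, size=n, p=pi))
    pool = [root_pool] if isinstance(root_pool, str) else list(root_pool)
    candidates = [s.upper() for s in pool if len(s) >= n]
    if not candidates:
        raise ValueError(f"root pool has no sequence of length >= {n}")
    for _ in range(1000):
        seq = candidates[int(rng.integers(len(candidates)))]
        start = int(rng.integers(len(seq) - n + 1))
        window = seq[start : start + n]
        if set(window) <= set(BASES):
            return window
    raise ValueError("could not draw an ACGT-only window from the root pool")


def simulate_dataset(
    params: EvolutionParams,
    rng: np.random.Generator | None = None,
    root_pool=None,
) -> SimulatedDataset:
    """Simulate one data set: root, blocks, branch-by-branch evolution,
    true-alignment assembly, and a fully resolved event log."""
    tree = params.tree
    if len(tree.leaves()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    root_seq = _draw_root(params, root_pool, rng)
    block_dist = params.block_length_dist or GeometricLength(50.0)
    block_map = place_conserved_blocks(
        len(root_seq), params.alpha, block_dist, rng, beta=params.beta
    )

    universe = _ColumnUniverse()
    root_cols = [universe.append() for _ in range(len(root_seq))]
    root_state = _BranchState(
        root_cols,
        [_BASE_INDEX[c] for c in root_seq],
        list(block_map.site_multipliers()),
    )

    events: list[Event] = []
    leaf_states: dict[str, _BranchState] = {}
    counter = [0]

    def branch_name(node) -> str:
        if node.name:
            return node.name
        counter[0] += 1
        return f"node{counter[0]}"

    def descend(node, state: _BranchState):
        for child_node in node.children:
            child_id = branch_name(child_node)
            child_state, branch_events = evolve_branch(
                state,
                child_node.length or 0.0,
                params,
                rng,
                branch_id=child_id,
                universe=universe,
            )
            events.extend(branch_events)
            if child_node.is_leaf:
                leaf_states[child_node.name] = child_state
            else:
                descend(child_node, child_state)

    descend(tree.root, root_state)

    order = universe.ordered()
    index = {id(col): i for i, col in enumerate(order)}
    n_cols = len(order)
    rows: dict[str, str] = {}
    for name, state in leaf_states.items():
        row = [GAP] * n_cols
        for col, base in zip(state.cols, state.bases):
            row[index[id(col)]] = BASES[base]
        rows[name] = "".join(row)

    for event in events:
        positions = [index[id(c)] for c in event.columns]
        event.columns = tuple(sorted(positions))
        event.aln_col_start = min(positions)
        event.aln_col_end = max(positions) + 1

    leaf_sequences = {name: state.text() for name, state in leaf_states.items()}
    dataset = SimulatedDataset(
        params, root_seq, block_map, leaf_sequences, rows, events
    )
    for name, seq in leaf_sequences.items():
        assert rows[name].replace(GAP, "") == seq, f"alignment row mismatch for {name}"
    return dataset


# ---------------------------------------------------------------------------
# Event-log I/O

_LOG_COLUMNS = [
    "branch_id",
    "kind",
    "time",
    "position",
    "length",
    "inserted_bases",
    "aln_col_start",
    "aln_col_end",
]


def write_event_log(path, events: Sequence[Event]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_LOG_COLUMNS) + "\n")
        for e in events:
            fh.write(
                f"{e.branch_id}\t{e.kind}\t{e.time:.9g}\t{e.position}\t{e.length}\t"
                f"{e.inserted_bases or '.'}\t{e.aln_col_start}\t{e.aln_col_end}\n"
            )


def read_event_log(path) -> list[Event]:
    events: list[Event] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LOG_COLUMNS:
            raise ValueError(f"unexpected event log header in {path}")
        for line in fh:
            branch_id, kind, time, pos, length, ins, start, end = line.rstrip("\n").split("\t")
            events.append(
                Event(
                    branch_id,
                    kind,
                    float(time),
                    int(pos),
                    int(length),
                    "" if ins == "." else ins,
                    columns=(),
                    aln_col_start=int(start),
                    aln_col_end=int(end),
                )
            )
    return events
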