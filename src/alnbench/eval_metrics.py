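"""Accuracy measures for predicted alignments and indel annotations.

Alignment measures (predicted vs true):

* agreement — fraction of residue-partner assignments (residue–residue and
  residue–gap, pooled over both rows of every unordered pair) identical
  between the predicted and true alignments;
* sensitivity — matched residue–residue pairs / true residue–residue pairs;
* specificity — matched residue–residue pairs / predicted residue–residue pairs.

Indel-annotation measures (per branch):

* ICA = |(N_Ie + N_De) − (N_It + N_Dt)| / (N_It + N_Dt)       (optimum 0)
* IRA = [N_Ie / (N_Ie + N_De)] / [N_It / (N_It + N_Dt)]        (optimum 1)
* IAC sensitivity/specificity over (column, kind) position items.

ICA and IRA closed forms are reconstructions consistent with the stated
optima; alternates can be supplied via the ``formula`` hooks if a different
source form is preferred.

Undefined ratios (0/0) are reported as ``None`` ("not applicable"), never
coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .evolver import Event
from .msa import GAP, MultipleAlignment

__all__ = [
    "PairScores",
    "AlignmentComparison",
    "IndelEvent",
    "IndelAnnotation",
    "compare_alignments",
    "indel_count_agreement",
    "indel_ratio_agreement",
    "indel_annotation_coverage",
    "annotation_from_events",
]

#: sentinel partner label for a residue sitting opposite a gap
GAP_PARTNER = -1


def partner_labels(alignment: MultipleAlignment, name_i: str, name_j: str):
    """Per-residue partner labels for one unordered row pair.

    Returns two lists: for each residue of row i (by ungapped index), the
    partner residue index in row j or :data:`GAP_PARTNER`; and vice versa.
    """
    row_i, row_j = alignment.row(name_i), alignment.row(name_j)
    partners_i: list[int] = []
    partners_j: list[int] = []
    pos_i = pos_j = 0
    for a, b in zip(row_i, row_j):
        if a != GAP and b != GAP:
            partners_i.append(pos_j)
            partners_j.append(pos_i)
            pos_i += 1
            pos_j += 1
        elif a != GAP:
            partners_i.append(GAP_PARTNER)
            pos_i += 1
        elif b != GAP:
            partners_j.append(GAP_PARTNER)
            pos_j += 1
    return partners_i, partners_j


def residue_pairs(alignment: MultipleAlignment, name_i: str, name_j: str) -> set[tuple[int, int]]:
    """Residue–residue homology pairs (ungapped indices) for one row pair."""
    partners_i, _ = partner_labels(alignment, name_i, name_j)
    return {(p, q) for p, q in enumerate(partners_i) if q != GAP_PARTNER}


@dataclass
class PairScores:
    agreement: float | None
    sensitivity: float | None
    specificity: float | None
    matched_pairs: int
    true_pairs: int
    predicted_pairs: int
    matched_labels: int
    total_labels: int


@dataclass
class AlignmentComparison:
    agreement: float | None
    sensitivity: float | None
    specificity: float | None
    per_pair: dict[tuple[str, str], PairScores] = field(default_factory=dict)
    matched_pairs: int = 0
    true_pairs: int = 0
    predicted_pairs: int = 0
    matched_labels: int = 0
    total_labels: int = 0


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compare_alignments(
    predicted: MultipleAlignment,
    truth: MultipleAlignment,
    average: str = "micro",
) -> AlignmentComparison:
    """Score a predicted alignment against the true alignment.

    Both alignments must cover the same taxa with identical ungapped
    sequences.  ``average`` selects the multi-species aggregation: ``micro``
    pools counts over all unordered pairs (default), ``macro`` averages the
    per-pair scores (pairs with undefined scores are skipped).
    """
    if average not in ("micro", "macro"):
        raise ValueError("average must be 'micro' or 'macro'")
    if set(predicted.names) != set(truth.names):
        raise ValueError("alignments cover different taxa")
    for name in predicted.names:
        if predicted.ungapped(name) != truth.ungapped(name):
            raise ValueError(f"ungapped sequence mismatch for {name!r}")

    per_pair: dict[tuple[str, str], PairScores] = {}
    totals = dict(matched_pairs=0, true_pairs=0, predicted_pairs=0,
                  matched_labels=0, total_labels=0)
    for name_i, name_j in combinations(sorted(predicted.names), 2):
        pred_i, pred_j = partner_labels(predicted, name_i, name_j)
        true_i, true_j = partner_labels(truth, name_i, name_j)
        matched_labels = sum(p == t for p, t in zip(pred_i, true_i)) + sum(
            p == t for p, t in zip(pred_j, true_j)
        )
        total_labels = len(pred_i) + len(pred_j)
        pred_pairs = {(p, q) for p, q in enumerate(pred_i) if q != GAP_PARTNER}
        true_pairs = {(p, q) for p, q in enumerate(true_i) if q != GAP_PARTNER}
        matched = len(pred_pairs & true_pairs)
        scores = PairScores(
            agreement=_ratio(matched_labels, total_labels),
            sensitivity=_ratio(matched, len(true_pairs)),
            specificity=_ratio(matched, len(pred_pairs)),
            matched_pairs=matched,
            true_pairs=len(true_pairs),
            predicted_pairs=len(pred_pairs),
            matched_labels=matched_labels,
            total_labels=total_labels,
        )
        per_pair[(name_i, name_j)] = scores
        totals["matched_pairs"] += matched
        totals["true_pairs"] += len(true_pairs)
        totals["predicted_pairs"] += len(pred_pairs)
        totals["matched_labels"] += matched_labels
        totals["total_labels"] += total_labels

    if average == "micro":
        agreement = _ratio(totals["matched_labels"], totals["total_labels"])
        sensitivity = _ratio(totals["matched_pairs"], totals["true_pairs"])
        specificity = _ratio(totals["matched_pairs"], totals["predicted_pairs"])
    else:
        def _mean(values):
            values = [v for v in values if v is not None]
            return sum(values) / len(values) if values else None

        agreement = _mean(s.agreement for s in per_pair.values())
        sensitivity = _mean(s.sensitivity for s in per_pair.values())
        specificity = _mean(s.specificity for s in per_pair.values())

    return AlignmentComparison(
        agreement, sensitivity, specificity, per_pair, **totals
    )


# ---------------------------------------------------------------------------
# Indel annotations

@dataclass(frozen=True)
class IndelEvent:
    branch_id: str
    kind: str                       # "insertion" | "deletion"
    columns: frozenset[int]

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if not self.columns:
            raise ValueError("indel event must span at least one column")


@dataclass
class IndelAnnotation:
    """Per-branch insertion/deletion events located on true-alignment columns."""

    events: list[IndelEvent] = field(default_factory=list)

    def branches(self) -> list[str]:
        return sorted({e.branch_id for e in self.events})

    def on_branch(self, branch_id: str) -> list[IndelEvent]:
        return [e for e in self.events if e.branch_id == branch_id]

    def counts(self, branch_id: str) -> tuple[int, int]:
        """(insertions, deletions) on one branch."""
        events = self.on_branch(branch_id)
        n_ins = sum(e.kind == "insertion" for e in events)
        return n_ins, len(events) - n_ins

    def positions(self, branch_id: str) -> set[tuple[int, str]]:
        """(column, kind) items covered by the branch's events."""
        return {
            (col, e.kind) for e in self.on_branch(branch_id) for col in e.columns
        }


def annotation_from_events(events: Iterable[Event], branches: Sequence[str] | None = None) -> IndelAnnotation:
    """Convert a simulator event log into the true indel annotation.

    In-memory events carry the exact column set of each indel.  Events read
    back from TSV only retain the column span; for those the half-open span
    ``[aln_col_start, aln_col_end)`` is used, which is exact unless insertions
    from other lineages interleaved inside the event's columns.
    """
    annotation = IndelAnnotation()
    for event in events:
        if event.kind not in ("insertion", "deletion"):
            continue
        if branches is not None and event.branch_id not in branches:
            continue
        columns = event.columns or tuple(range(event.aln_col_start, event.aln_col_end))
        annotation.events.append(
            IndelEvent(event.branch_id, event.kind, frozenset(columns))
        )
    return annotation


def indel_count_agreement(
    truth: IndelAnnotation, predicted: IndelAnnotation, branch_id: str
) -> float | None:
    """ICA = |(N_Ie + N_De) − (N_It + N_Dt)| / (N_It + N_Dt); optimum 0."""
    n_it, n_dt = truth.counts(branch_id)
    n_ie, n_de = predicted.counts(branch_id)
    if n_it + n_dt == 0:
        return None
    return abs((n_ie + n_de) - (n_it + n_dt)) / (n_it + n_dt)


def indel_ratio_agreement(
    truth: IndelAnnotation, predicted: IndelAnnotation, branch_id: str
) -> float | None:
    """IRA = [N_Ie/(N_Ie+N_De)] / [N_It/(N_It+N_Dt)]; optimum 1."""
    n_it, n_dt = truth.counts(branch_id)
    n_ie, n_de = predicted.counts(branch_id)
    if n_ie + n_de == 0 or n_it + n_dt == 0 or n_it == 0:
        return None
    return (n_ie / (n_ie + n_de)) / (n_it / (n_it + n_dt))


def indel_annotation_coverage(
    truth: IndelAnnotation, predicted: IndelAnnotation, branch_id: str
) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) of predicted (column, kind) position items."""
    t = truth.positions(branch_id)
    p = predicted.positions(branch_id)
    matched = len(t & p)
    return (_ratio(matched, len(t)), _ratio(matched, len(p)))


# ---------------------------------------------------------------------------
# Stratified summaries (insertion-excess vs deletion-excess data sets)

def stratify_by_indel_bias(
    dataset_bias: Mapping[str, tuple[float, float]],
    dataset_scores: Mapping[str, float | None],
    factor: float = 2.0,
):
    """Split per-data-set scores into insertion-excess and deletion-excess strata.

    ``dataset_bias`` maps data set id to (expected insertions, expected
    deletions); a data set enters a stratum when one expectation is at least
    ``factor`` times the other.  Returns ``{"insertion_excess": [...],
    "deletion_excess": [...]}`` score lists (None scores skipped).
    """
    strata: dict[str, list[float]] = {"insertion_excess": [], "deletion_excess": []}
    for ds_id, (e_ins, e_del) in dataset_bias.items():
        score = dataset_scores.get(ds_id)
        if score is None:
            continue
        if e_ins >= factor * e_del:
            strata["insertion_excess"].append(score)
        elif e_del >= factor * e_ins:
            strata["deletion_excess"].append(score)
    return strata
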