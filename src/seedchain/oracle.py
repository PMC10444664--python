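"""Ground-truth machinery: unit-cost global alignment and evaluation.

This module supplies the exact counterpart of the chain estimator: a
Levenshtein dynamic-programming alignment with traceback, the optimal
alignment identity it implies, the number of seeds readable from the
optimal alignment's match runs, and the confusion matrix comparing the
estimator's reported pair set with the ground-truth set at an identity
threshold.

The DP fills an (m+1) x (n+1) distance matrix row by row with numpy.
The within-row dependency of the insertion move is resolved with a
running minimum: row[j] = min_{j' <= j} (candidate[j'] + (j - j')),
computed as an accumulated minimum over candidate[j'] - j'.  Traceback
prefers, in order, match/substitution, deletion, insertion, which makes
the returned alignment (and hence the identity among co-optimal
alignments) deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import GapAccount, estimate_identity
from .select import KSelection

__all__ = [
    "GAP",
    "TruthRecord",
    "ConfusionCounts",
    "edit_distance",
    "edit_distance_align",
    "alignment_gap_account",
    "optimal_identity",
    "optimal_seed_count",
    "classify",
    "classify_labeled",
    "within_tolerance",
]

#: Gap symbol used in alignment columns.
GAP = "-"


@dataclass
class TruthRecord:
    """An optimal alignment of one sequence pair and derived truths.

    ``alignment`` is a list of columns (a, b) over letters and the gap
    symbol: (a, -) is a deletion from the first sequence, (-, b) an
    insertion, (a, b) with a != b a substitution.  The column costs sum
    to ``edit_distance`` by construction.
    """

    edit_distance: int
    alignment: list[tuple[str, str]]
    optimal_identity: float
    seed_count_k: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _dp_matrix(x: str, y: str) -> np.ndarray:
    """Full unit-cost edit-distance matrix, rows indexed by x."""
    m, n = len(x), len(y)
    yb = np.frombuffer(y.encode("ascii"), dtype=np.uint8)
    cols = np.arange(n + 1, dtype=np.int32)
    dist = np.empty((m + 1, n + 1), dtype=np.int32)
    dist[0] = cols
    for i in range(1, m + 1):
        prev = dist[i - 1]
        cand = np.empty(n + 1, dtype=np.int32)
        cand[0] = i
        sub = prev[:-1] + (yb != ord(x[i - 1]))
        np.minimum(prev[1:] + 1, sub, out=cand[1:])
        # resolve the left-to-right insertion dependency in one pass
        dist[i] = np.minimum.accumulate(cand - cols) + cols
    return dist


def edit_distance(x: str, y: str) -> int:
    """Levenshtein distance between two strings."""
    if not x or not y:
        return max(len(x), len(y))
    return int(_dp_matrix(x, y)[len(x), len(y)])


def edit_distance_align(x: str, y: str) -> TruthRecord:
    """Distance plus one deterministic optimal alignment with traceback."""
    if not x or not y:
        raise ValueError("both sequences must be non-empty")
    dist = _dp_matrix(x, y)
    columns: list[tuple[str, str]] = []
    i, j = len(x), len(y)
    while i > 0 or j > 0:
        here = dist[i, j]
        if (
            i > 0
            and j > 0
            and here == dist[i - 1, j - 1] + (x[i - 1] != y[j - 1])
        ):
            columns.append((x[i - 1], y[j - 1]))
            i -= 1
            j -= 1
        elif i > 0 and here == dist[i - 1, j] + 1:
            columns.append((x[i - 1], GAP))
            i -= 1
        else:
            columns.append((GAP, y[j - 1]))
            j -= 1
    columns.reverse()
    record = TruthRecord(
        edit_distance=int(dist[len(x), len(y)]),
        alignment=columns,
        optimal_identity=0.0,
    )
    record.optimal_identity = optimal_identity(record, len(x))
    return record


def alignment_gap_account(alignment: list[tuple[str, str]]) -> GapAccount:
    """Count substitutions, deletions and insertions in alignment columns."""
    subs = dels = ins = 0
    for a, b in alignment:
        if a == GAP:
            ins += 1
        elif b == GAP:
            dels += 1
        elif a != b:
            subs += 1
    return GapAccount(subs, dels, ins)


def optimal_identity(record: TruthRecord, m: int) -> float:
    """Alignment identity of the record's alignment, from its gap counts.

    Same formula as the chain estimator: (m - (sub + del)) / (m + ins),
    with m the length of the first sequence.
    """
    return estimate_identity(alignment_gap_account(record.alignment), m)


def optimal_seed_count(record: TruthRecord, k: int) -> int:
    """Number of k-length seeds readable from the optimal alignment.

    The alignment is decomposed into maximal runs of consecutive match
    columns; a run of length L contributes max(0, L - k + 1) seeds,
    exactly as a pair of identical length-L fragments would.  Results
    are cached on the record.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k in record.seed_count_k:
        return record.seed_count_k[k]
    count = 0
    run = 0
    for a, b in record.alignment + [(GAP, GAP)]:
        if a == b and a != GAP:
            run += 1
        else:
            count += max(0, run - k + 1)
            run = 0
    record.seed_count_k[k] = count
    return count


def classify(
    selections: list[KSelection],
    truth_records: list[TruthRecord],
    e: float,
) -> ConfusionCounts:
    """Confusion matrix of the estimator's pair set against ground truth.

    A pair is predicted positive when its best estimated identity over
    the k scan reaches ``e``; it is truly positive when its optimal
    alignment identity does.  ``selections`` and ``truth_records`` must
    be parallel lists over the same pairs.
    """
    if len(selections) != len(truth_records):
        raise ValueError(
            f"mismatched pair sets: {len(selections)} selections vs "
            f"{len(truth_records)} truth records"
        )
    tp = fp = tn = fn = 0
    for sel, truth in zip(selections, truth_records):
        predicted = sel.e_best >= e
        actual = truth.optimal_identity >= e
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def classify_labeled(
    selections: list[KSelection],
    labels: list[bool],
    e: float,
) -> ConfusionCounts:
    """Confusion matrix against externally supplied ground-truth labels.

    Used by the synthetic evaluation harness, where a pair's truth is
    its generating condition (low-divergence pairs are the positives)
    rather than a recomputed optimal identity.
    """
    if len(selections) != len(labels):
        raise ValueError(
            f"mismatched pair sets: {len(selections)} selections vs "
            f"{len(labels)} labels"
        )
    tp = fp = tn = fn = 0
    for sel, actual in zip(selections, labels):
        predicted = sel.e_best >= e
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def within_tolerance(
    t_estimated: int, t_optimal: int, tol: float = 0.10
) -> bool:
    """True iff the estimated seed count is within +-tol of the optimum.

    With ``t_optimal`` = 0 this is true only for an estimate of 0.
    """
    if t_optimal < 0:
        raise ValueError("t_optimal must be >= 0")
    return abs(t_estimated - t_optimal) <= tol * t_optimal
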