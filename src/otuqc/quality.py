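"""Database-independent quality assessment of OTU assignments.

The assessment asks, for every unordered pair of sequences, two binary
questions: is the observed pairwise dissimilarity at or below the
evaluation threshold ("similar"), and did the clustering place the pair in
the same OTU ("together")?  Crossing the answers yields pair-level
confusion counts:

* TP — similar and together (correctly grouped)
* FN — similar but apart (over-split)
* FP — distant but together (over-lumped)
* TN — distant and apart (correctly separated)

The Matthews correlation coefficient summarises the four counts in one
number in [-1, 1]:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with sensitivity TP/(TP+FN) and specificity TN/(TN+FP) as companions.
The metric needs only the distance matrix and the partition — no taxonomy
and no reference database — so it applies to a clustering from any tool.

Pair classification uses a closed interval at the threshold: a pair at
exactly 0.03 belongs inside a 3% OTU.  Absent pairs of a sparse matrix
count as "distant", which is sound because the evaluation threshold is
required not to exceed the matrix storage cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clustering import OTUPartition, cluster, partition_at
from .distance import DistanceMatrix
from .errors import UsageError

#: Default threshold sweep grid: 0.00-0.10 in steps of 0.01, bracketing
#: the conventional 3% OTU definition.
DEFAULT_SWEEP_GRID = tuple(round(0.01 * i, 2) for i in range(11))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pair counts at an evaluation threshold."""

    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float
    n_sequences: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise UsageError("confusion counts must be non-negative")
        total = self.n_sequences * (self.n_sequences - 1) // 2
        if self.tp + self.tn + self.fp + self.fn != total:
            raise UsageError(
                f"counts sum to {self.tp + self.tn + self.fp + self.fn}, "
                f"expected n(n-1)/2 = {total} for n = {self.n_sequences}"
            )

    @property
    def total_pairs(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class QualityReport:
    """MCC, sensitivity and specificity for one (partition, matrix, threshold).

    ``sensitivity_defined`` / ``specificity_defined`` flag whether the
    corresponding ratio had a non-zero denominator; an undefined ratio is
    reported as 1.0 (there was nothing to miss).
    """

    counts: ConfusionCounts
    mcc: float
    sensitivity: float
    specificity: float
    sensitivity_defined: bool = True
    specificity_defined: bool = True


def confusion_counts(
    partition: OTUPartition, matrix: DistanceMatrix, threshold: float
) -> ConfusionCounts:
    """Exact pair-level confusion counts for a partition against a matrix.

    Every partition member must be a matrix name and the threshold must
    not exceed the matrix storage cutoff (else absent pairs would be
    ambiguous).  Counting is exact over all n(n-1)/2 pairs of the
    partition's sequences.
    """
    matrix.require_cutoff(threshold)
    name_set = set(partition.names)
    missing = name_set - set(matrix.names)
    if missing:
        raise UsageError(
            f"partition members absent from the distance matrix: "
            f"{sorted(missing)[:3]}"
        )
    n = len(name_set)
    total = n * (n - 1) // 2

    # TP from within-OTU pairs; "similar" pair total from stored entries.
    tp = 0
    within = 0
    for otu in partition.otus:
        otu_members = sorted(otu)
        k = len(otu_members)
        within += k * (k - 1) // 2
        for i in range(k - 1):
            a = otu_members[i]
            for j in range(i + 1, k):
                d = matrix.get(a, otu_members[j])
                if d is not None and d <= threshold:
                    tp += 1

    covers_all = len(name_set) == matrix.n
    similar = 0
    for a, b, d in matrix.iter_pairs():
        if d <= threshold and (covers_all or (a in name_set and b in name_set)):
            similar += 1

    fp = within - tp
    fn = similar - tp
    tn = total - tp - fp - fn
    return ConfusionCounts(tp, tn, fp, fn, threshold, n)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient of pair-level confusion counts.

    The numerator and the radicand are formed in exact integer arithmetic
    before the single final division, so counts up to ~10^12 pairs do not
    overflow or lose precision.

    Zero-denominator convention: a partition with no false positives and
    no false negatives is a perfect clustering and scores 1.0 (this covers
    the all-singleton, all-distant case); any other vanishing marginal
    scores 0.0 (no correlation is expressible).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if fp == 0 and fn == 0:
        return 1.0
    radicand = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if radicand == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(radicand)


def evaluate(
    partition: OTUPartition, matrix: DistanceMatrix, threshold: float
) -> QualityReport:
    """Confusion counts plus MCC, sensitivity and specificity."""
    counts = confusion_counts(partition, matrix, threshold)
    sens_den = counts.tp + counts.fn
    spec_den = counts.tn + counts.fp
    return QualityReport(
        counts=counts,
        mcc=mcc(counts),
        sensitivity=counts.tp / sens_den if sens_den else 1.0,
        specificity=counts.tn / spec_den if spec_den else 1.0,
        sensitivity_defined=sens_den > 0,
        specificity_defined=spec_den > 0,
    )


def best_threshold(
    partition: OTUPartition,
    matrix: DistanceMatrix,
    thresholds: Sequence[float] = DEFAULT_SWEEP_GRID,
) -> tuple[float, float]:
    """Grid threshold maximising MCC; ties go to the smallest threshold."""
    if len(thresholds) == 0:
        raise UsageError("threshold grid must be non-empty")
    best_t: Optional[float] = None
    best_m = -math.inf
    for t in sorted(thresholds):
        m = mcc(confusion_counts(partition, matrix, t))
        if m > best_m:
            best_t, best_m = t, m
    assert best_t is not None
    return best_t, best_m


@dataclass(frozen=True)
class StabilityResult:
    """MCC values across seeded input-order randomizations."""

    mcc_values: list[float]
    seed: Optional[int]

    @property
    def min(self) -> float:
        return min(self.mcc_values)

    @property
    def max(self) -> float:
        return max(self.mcc_values)

    @property
    def range(self) -> float:
        return self.max - self.min


def stability(
    matrix: DistanceMatrix,
    method: str,
    cutoff: float,
    threshold: float,
    n_shuffles: int = 30,
    seed: Optional[int] = None,
    precision: int = 100,
) -> StabilityResult:
    """Re-cluster under randomized sequence input orders and collect MCC.

    Each shuffle permutes the matrix name order (the distances are
    unchanged), re-runs the clusterer at ``cutoff``, takes the partition
    at the ``threshold`` label, and evaluates it at ``threshold``.  For an
    input-order-invariant clusterer the reported range is exactly 0.
    """
    if n_shuffles < 1:
        raise UsageError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    names = np.array(matrix.names)
    for _ in range(n_shuffles):
        order = [str(x) for x in rng.permutation(names)]
        shuffled = matrix.reorder(order)
        partitions = cluster(shuffled, method, cutoff, precision)
        part = partition_at(partitions, threshold)
        values.append(evaluate(part, shuffled, threshold).mcc)
    return StabilityResult(values, seed)
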