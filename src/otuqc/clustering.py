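"""De novo hierarchical agglomerative clustering of sequences into OTUs.

Three linkage rules are provided, under their amplicon-field names:
nearest neighbor (single linkage: minimum cross-cluster pair distance),
furthest neighbor (complete linkage: maximum), and average neighbor
(UPGMA: unweighted arithmetic mean over all cross-cluster pairs).

The clusterer operates on a sparse :class:`~otuqc.distance.DistanceMatrix`.
A cross-cluster pair absent from the matrix is known only to exceed the
storage cutoff, so it enters linkage as ``storage_cutoff + EPS``: under
furthest and average linkage this conservatively pushes clusters apart,
and under nearest linkage absent pairs simply cannot be the minimum.
Requesting a clustering cutoff beyond the storage cutoff raises
:class:`~otuqc.errors.SparsityError` — the answer would depend on
distances the matrix does not hold.

Ties (several cluster pairs at the same minimum distance) are broken by
the lexicographically smallest pair of cluster representative names, where
a cluster is represented by its smallest member name.  The representative
pair is a content-derived key, so the whole merge sequence — and therefore
every emitted partition — is invariant under permutations of the input
order.

Merge heights are reported on a rounded label ladder: height ``h`` falls
under label ``floor(h * precision + 0.5) / precision`` and consecutive
merges sharing a rounded label collapse into one reported partition.  The
first partition is always ``"unique"`` (all singletons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .distance import DistanceMatrix
from .errors import FormatError, UsageError

#: Margin added to the storage cutoff when an absent pair enters a linkage
#: average; any positive value keeps unmergeable pairs unmergeable.
EPS = 1e-6

LINKAGE_METHODS = ("nearest", "average", "furthest")


@dataclass(frozen=True)
class OTUPartition:
    """A labelled partition of sequence names into OTUs.

    ``label`` is a rounded distance label such as ``"0.03"``, or
    ``"unique"`` for the all-singleton partition.  OTUs are disjoint,
    non-empty, and jointly cover the full name set.
    """

    label: str
    otus: list[frozenset[str]]

    def __post_init__(self) -> None:
        total = 0
        universe: set[str] = set()
        for otu in self.otus:
            if not otu:
                raise UsageError("empty OTU in partition")
            total += len(otu)
            universe |= otu
        if total != len(universe):
            raise UsageError("OTUs are not disjoint")

    @property
    def names(self) -> frozenset[str]:
        out: set[str] = set()
        for otu in self.otus:
            out |= otu
        return frozenset(out)

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUPartition):
            return NotImplemented
        return self.label == other.label and set(self.otus) == set(other.otus)

    def __hash__(self) -> int:
        return hash((self.label, frozenset(self.otus)))


def _label_value(label: str) -> float:
    return -1.0 if label == "unique" else float(label)


def _format_label(height: float, precision: int) -> str:
    rounded = math.floor(height * precision + 0.5) / precision
    decimals = max(0, len(str(precision)) - 1)
    return f"{rounded:.{decimals}f}"


@dataclass
class _PairStats:
    """Aggregated stored cross-cluster pair statistics for one cluster pair."""

    count: int
    dmin: float
    dmax: float
    dsum: float

    def merged(self, other: "_PairStats") -> "_PairStats":
        return _PairStats(
            self.count + other.count,
            min(self.dmin, other.dmin),
            max(self.dmax, other.dmax),
            self.dsum + other.dsum,
        )


def _linkage_distance(
    method: str, stats: _PairStats, size_product: int, penalty: float
) -> float:
    if method == "nearest":
        return stats.dmin
    if method == "furthest":
        return penalty if stats.count < size_product else stats.dmax
    # average: absent pairs contribute the penalty value
    return (stats.dsum + (size_product - stats.count) * penalty) / size_product


def cluster(
    matrix: DistanceMatrix,
    method: str,
    cutoff: float,
    precision: int = 100,
) -> list[OTUPartition]:
    """Agglomeratively cluster up to ``cutoff``, emitting labelled partitions.

    Merging continues while the smallest inter-cluster distance is
    <= ``cutoff``.  Returns the ``"unique"`` partition followed by one
    partition per distinct rounded merge label, in merge order.

    Raises
    ------
    SparsityError
        If ``cutoff`` exceeds the matrix storage cutoff.
    UsageError
        For an unknown linkage method or non-positive precision.
    """
    if method not in LINKAGE_METHODS:
        raise UsageError(f"unknown linkage method {method!r}; use {LINKAGE_METHODS}")
    if precision < 1:
        raise UsageError("precision must be a positive integer")
    matrix.require_cutoff(cutoff)
    penalty = matrix.storage_cutoff + EPS

    # Cluster id = smallest member name (unique, content-derived).
    members: dict[str, set[str]] = {name: {name} for name in matrix.names}
    stats: dict[tuple[str, str], _PairStats] = {}
    for a, b, d in matrix.iter_pairs():
        key = (a, b) if a <= b else (b, a)
        stats[key] = _PairStats(1, d, d, d)

    merges: list[tuple[float, str, str]] = []  # (height, surviving id, absorbed id)
    while stats:
        best_key: Optional[tuple[str, str]] = None
        best_dist = math.inf
        for key, st in stats.items():
            d = _linkage_distance(
                method, st, len(members[key[0]]) * len(members[key[1]]), penalty
            )
            if d < best_dist or (d == best_dist and (best_key is None or key < best_key)):
                best_dist = d
                best_key = key
        if best_key is None or best_dist > cutoff:
            break
        keep, gone = best_key  # keep < gone, so keep remains the smallest member
        members[keep] |= members.pop(gone)
        merged_stats: dict[str, _PairStats] = {}
        for other in list(members):
            if other in (keep, gone):
                continue
            parts = []
            for cid in (keep, gone):
                key = (cid, other) if cid <= other else (other, cid)
                st = stats.pop(key, None)
                if st is not None:
                    parts.append(st)
            if parts:
                combined = parts[0] if len(parts) == 1 else parts[0].merged(parts[1])
                merged_stats[other] = combined
        stats.pop(best_key, None)
        for other, st in merged_stats.items():
            key = (keep, other) if keep <= other else (other, keep)
            stats[key] = st
        merges.append((best_dist, keep, gone))

    return _partitions_from_merges(matrix.names, merges, precision)


def _canonical_otus(members: Iterable[set[str]]) -> list[frozenset[str]]:
    return [frozenset(m) for m in sorted(members, key=min)]


def _partitions_from_merges(
    names: Sequence[str],
    merges: Sequence[tuple[float, str, str]],
    precision: int,
) -> list[OTUPartition]:
    clusters: dict[str, set[str]] = {n: {n} for n in names}
    out = [OTUPartition("unique", _canonical_otus(clusters.values()))]
    pending_label: Optional[str] = None
    for i, (height, keep, gone) in enumerate(merges):
        clusters[keep] = clusters[keep] | clusters.pop(gone)
        label = _format_label(height, precision)
        next_label = (
            _format_label(merges[i + 1][0], precision) if i + 1 < len(merges) else None
        )
        pending_label = label
        if next_label != label:
            out.append(OTUPartition(pending_label, _canonical_otus(clusters.values())))
            pending_label = None
    return out


def partition_at(
    partitions: Sequence[OTUPartition], label: Union[str, float]
) -> OTUPartition:
    """Partition at the largest rounded label <= the requested label.

    Follows the standard list-file convention: asking for 0.02 when the
    ladder holds {unique, 0.01, 0.03} returns the 0.01 partition.  Falls
    back to the ``"unique"`` partition when nothing else qualifies.
    """
    if not partitions:
        raise UsageError("no partitions given")
    want = _label_value(label) if isinstance(label, str) else float(label)
    best = None
    best_val = -math.inf
    for part in partitions:
        val = _label_value(part.label)
        if val <= want + 1e-12 and val > best_val:
            best = part
            best_val = val
    if best is None:  # pragma: no cover - "unique" (-1.0) always qualifies
        best = partitions[0]
    return best


def write_list(partitions: Sequence[OTUPartition], path) -> None:
    """Write partitions in the mothur-style list dialect.

    One line per label: label, OTU count, then one comma-separated member
    group per OTU, all tab-separated.  Members and groups are emitted in
    canonical (lexicographic) order so output is input-order invariant.
    """
    with open(path, "w") as fh:
        for part in partitions:
            groups = [",".join(sorted(otu)) for otu in part.otus]
            fh.write("\t".join([part.label, str(len(groups)), *groups]) + "\n")


def read_list(path) -> list[OTUPartition]:
    """Read the list dialect written by :func:`write_list` (or by mothur)."""
    partitions: list[OTUPartition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected label and OTU count")
            label, raw_count = fields[0], fields[1]
            try:
                count = int(raw_count)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: bad OTU count {raw_count!r}"
                ) from None
            groups = fields[2:]
            if len(groups) != count:
                raise FormatError(
                    f"{path}:{lineno}: declares {count} OTUs but lists {len(groups)}"
                )
            otus = [frozenset(g.split(",")) for g in groups]
            for otu in otus:
                if "" in otu:
                    raise FormatError(f"{path}:{lineno}: empty member name")
            partitions.append(OTUPartition(label, otus))
    if not partitions:
        raise FormatError(f"{path}: no partitions found")
    return partitions
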