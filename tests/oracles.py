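"""Independent brute-force oracles used to validate the implementation.

Everything here recomputes quantities from first principles — double loops
over pairs, O(n^3) agglomeration with from-scratch linkage evaluation,
graph connected components — and deliberately shares no code path with
the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from otuqc.clustering import EPS, OTUPartition
from otuqc.distance import DistanceMatrix


def brute_confusion(
    partition: OTUPartition, matrix: DistanceMatrix, threshold: float
) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) by explicit enumeration of every unordered pair."""
    names = sorted(partition.names)
    group = {}
    for gid, otu in enumerate(partition.otus):
        for name in otu:
            group[name] = gid
    tp = tn = fp = fn = 0
    for a, b in itertools.combinations(names, 2):
        d = matrix.get(a, b)
        similar = d is not None and d <= threshold
        together = group[a] == group[b]
        if similar and together:
            tp += 1
        elif similar:
            fn += 1
        elif together:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def brute_mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    if fp == 0 and fn == 0:
        return 1.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)


def components_partition(matrix: DistanceMatrix, threshold: float) -> set[frozenset]:
    """Connected components of the <=threshold graph (scipy csgraph)."""
    idx = {name: i for i, name in enumerate(matrix.names)}
    rows, cols = [], []
    for a, b, d in matrix.iter_pairs():
        if d <= threshold:
            rows.append(idx[a])
            cols.append(idx[b])
    n = matrix.n
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, set[str]] = {}
    for name, lab in zip(matrix.names, labels):
        groups.setdefault(int(lab), set()).add(name)
    return {frozenset(g) for g in groups.values()}


def _naive_linkage_distance(
    method: str, ca: set, cb: set, matrix: DistanceMatrix, penalty: float
) -> float:
    vals = []
    absent = 0
    for x in ca:
        for y in cb:
            d = matrix.get(x, y)
            if d is None:
                absent += 1
            else:
                vals.append(d)
    if method == "nearest":
        return min(vals) if vals else math.inf
    if method == "furthest":
        return penalty if absent else max(vals)
    return (sum(vals) + absent * penalty) / (len(vals) + absent)


def naive_cluster(
    matrix: DistanceMatrix, method: str, cutoff: float, precision: int = 100
) -> list[OTUPartition]:
    """O(n^3) agglomeration evaluating every cluster-pair from scratch.

    Same contracts as otuqc.clustering.cluster (penalty for absent pairs,
    representative-name tie rule, rounded label ladder) but none of its
    incremental bookkeeping.
    """
    penalty = matrix.storage_cutoff + EPS
    clusters: list[set] = [{n} for n in matrix.names]
    snapshots: list[tuple[float, set[frozenset]]] = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = _naive_linkage_distance(method, clusters[i], clusters[j], matrix, penalty)
            rep = tuple(sorted((min(clusters[i]), min(clusters[j]))))
            key = (d, rep)
            if best is None or key < best[0]:
                best = (key, i, j)
        (d, _), i, j = best
        if d > cutoff:
            break
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        snapshots.append((d, {frozenset(c) for c in clusters}))

    def fmt(h: float) -> str:
        r = math.floor(h * precision + 0.5) / precision
        dec = max(0, len(str(precision)) - 1)
        return f"{r:.{dec}f}"

    out = [
        OTUPartition(
            "unique", [frozenset({n}) for n in sorted(matrix.names)]
        )
    ]
    for k, (h, snap) in enumerate(snapshots):
        label = fmt(h)
        next_label = fmt(snapshots[k + 1][0]) if k + 1 < len(snapshots) else None
        if next_label != label:
            out.append(OTUPartition(label, sorted(snap, key=min)))
    return out


def random_instance(rng: np.random.Generator, n: int, dense: bool = True):
    """A random dense matrix plus a random partition over the same names."""
    names = [f"s{i:03d}" for i in range(n)]
    matrix = DistanceMatrix(names, 1.0)
    for a, b in itertools.combinations(names, 2):
        matrix.set(a, b, float(rng.integers(0, 1001)) / 1000.0)
    k = int(rng.integers(1, n + 1))
    assignment = rng.integers(0, k, size=n)
    groups: dict[int, set[str]] = {}
    for name, g in zip(names, assignment):
        groups.setdefault(int(g), set()).add(name)
    partition = OTUPartition("0.03", [frozenset(g) for g in groups.values()])
    return partition, matrix
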