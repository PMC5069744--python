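import itertools

import numpy as np
import pytest

from otuqc.distance import DistanceMatrix
from otuqc.seqio import AlignedSequenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(20160426)


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">s1 some description\nACGT\n>s2\nAC-T\n")
    return path


def make_dense_matrix(names, distances):
    """Dense DistanceMatrix from {(a, b): d} (pairs in any order)."""
    m = DistanceMatrix(list(names), 1.0)
    for (a, b), d in distances.items():
        m.set(a, b, d)
    expected = len(names) * (len(names) - 1) // 2
    assert len(m) == expected, "fixture must specify every pair"
    return m


def random_sequences(rng, n, length, alphabet="ACGT"):
    letters = np.array(list(alphabet))
    return [
        "".join(letters[rng.integers(0, len(letters), size=length)])
        for _ in range(n)
    ]


@pytest.fixture
def two_clique_instance():
    """Two perfect OTUs: tight cliques at 0.01, separated by 0.20."""
    names = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    dists = {}
    for x, y in itertools.combinations(names, 2):
        same = x[0] == y[0]
        dists[(x, y)] = 0.01 if same else 0.20
    matrix = make_dense_matrix(names, dists)
    from otuqc.clustering import OTUPartition

    partition = OTUPartition(
        "0.03",
        [frozenset(n for n in names if n[0] == "a"),
         frozenset(n for n in names if n[0] == "b")],
    )
    return partition, matrix


@pytest.fixture
def aligned_set():
    return AlignedSequenceSet(
        ["q1", "q2", "q3"],
        ["ACGTACGTAC", "ACGTACGTAG", "TTTTACGTAC"],
    )
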