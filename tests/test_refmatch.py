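import itertools

import pytest

from otuqc.errors import AlignmentError, UsageError
from otuqc.refmatch import (
    UNASSIGNED,
    ReferenceAssignment,
    exhaustive_assign,
    greedy_assign,
    matcher_metrics,
    shuffle_experiment,
    within_otu_spread,
)
from otuqc.distance import pairwise_distance
from otuqc.seqio import AlignedSequenceSet
from otuqc.simulate import generate_reference_pool
from tests.conftest import random_sequences


def mutate(seq, positions, base_map=None):
    """Substitute the given positions to a different base."""
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = (base_map or rot)[out[p]]
    return "".join(out)


@pytest.fixture
def two_hit_fixture():
    """One query within 0.03 of two references, plus an unmatchable query."""
    base = ("ACGT" * 25)
    r2 = mutate(base, [10])
    r7 = mutate(base, [20])
    far = "T" * 100
    refs = AlignedSequenceSet(["r2", "r7", "rfar"], [r2, r7, far])
    queries = AlignedSequenceSet(["qhit", "qmiss"], [base, mutate(base, range(50))])
    return queries, refs


class TestExhaustiveAssign:
    def test_identical_query_gets_its_reference(self, rng):
        refs = AlignedSequenceSet(
            [f"r{i}" for i in range(5)], random_sequences(rng, 5, 80)
        )
        queries = AlignedSequenceSet(["q"], [refs.sequences[3]])
        out = exhaustive_assign(queries, refs, 0.03)
        assert out.assignments["q"] == "r3"

    def test_distant_query_unassigned(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        out = exhaustive_assign(queries, refs, 0.03)
        assert out.assignments["qmiss"] == UNASSIGNED
        assert out.matched_count == 1

    def test_tie_breaks_to_smallest_reference_name(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        out = exhaustive_assign(queries, refs, 0.03)
        assert out.assignments["qhit"] == "r2"  # both refs at 0.01

    def test_order_invariant_under_ten_shuffles(self, rng):
        """Identical assignments for any permutation of queries and refs."""
        refs = AlignedSequenceSet(
            [f"r{i}" for i in range(10)], random_sequences(rng, 10, 60)
        )
        queries = AlignedSequenceSet(
            [f"q{i}" for i in range(20)],
            [mutate(refs.sequences[i % 10], [int(rng.integers(0, 60))])
             for i in range(20)],
        )
        baseline = exhaustive_assign(queries, refs, 0.05)
        for _ in range(10):
            r_order = [str(x) for x in rng.permutation(refs.names)]
            q_order = [str(x) for x in rng.permutation(queries.names)]
            again = exhaustive_assign(
                queries.reorder(q_order), refs.reorder(r_order), 0.05
            )
            assert again.assignments == baseline.assignments

    def test_alignment_length_mismatch_rejected(self):
        refs = AlignedSequenceSet(["r"], ["ACGT"])
        queries = AlignedSequenceSet(["q"], ["ACGTA"])
        with pytest.raises(AlignmentError):
            exhaustive_assign(queries, refs)


class TestGreedyAssign:
    def test_first_hit_depends_on_order(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        first = greedy_assign(queries, refs, 0.03, ["r7", "rfar", "r2"])
        second = greedy_assign(queries, refs, 0.03, ["r2", "rfar", "r7"])
        assert first.assignments["qhit"] == "r7"
        assert second.assignments["qhit"] == "r2"
        assert first.matched_count == second.matched_count == 1

    def test_no_hit_unassigned_under_every_order(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        for order in itertools.permutations(refs.names):
            out = greedy_assign(queries, refs, 0.03, list(order))
            assert out.assignments["qmiss"] == UNASSIGNED

    def test_single_reference_equals_exhaustive(self, rng):
        refs = AlignedSequenceSet(["r"], random_sequences(rng, 1, 50))
        queries = AlignedSequenceSet(
            ["q1", "q2"], [refs.sequences[0], mutate(refs.sequences[0], range(20))]
        )
        assert (
            greedy_assign(queries, refs, 0.03).assignments
            == exhaustive_assign(queries, refs, 0.03).assignments
        )

    def test_assignments_respect_threshold(self, rng):
        refs = AlignedSequenceSet(
            [f"r{i}" for i in range(6)], random_sequences(rng, 6, 50)
        )
        queries = AlignedSequenceSet(
            [f"q{i}" for i in range(12)], random_sequences(rng, 12, 50)
        )
        out = greedy_assign(queries, refs, 0.4)
        for q, r in out.matched.items():
            assert pairwise_distance(queries.get(q), refs.get(r)) <= 0.4

    def test_bad_order_rejected(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        with pytest.raises(UsageError):
            greedy_assign(queries, refs, 0.03, ["r2", "r7"])


class TestShuffleExperiment:
    def test_exhaustive_matcher_range_is_flat(self, rng):
        refs = AlignedSequenceSet(
            [f"r{i}" for i in range(8)], random_sequences(rng, 8, 60)
        )
        queries = AlignedSequenceSet(
            [f"q{i}" for i in range(10)],
            [mutate(refs.sequences[i % 8], [i]) for i in range(10)],
        )
        result = shuffle_experiment(
            queries, refs, 0.05, n_shuffles=10, seed=4, matcher="exhaustive"
        )
        assert result.min_matched == result.max_matched
        assert not result.identity_varied

    def test_greedy_identity_varies_on_two_hit_fixture(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        result = shuffle_experiment(
            queries, refs, 0.03, n_shuffles=20, seed=4, matcher="greedy"
        )
        assert result.min_matched == result.max_matched == 1
        assert result.identity_varied
        winners = {r.assignments["qhit"] for r in result.per_shuffle}
        assert winners == {"r2", "r7"}

    def test_same_seed_reproduces_all_outputs(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        a = shuffle_experiment(queries, refs, 0.03, 8, seed=17, matcher="greedy")
        b = shuffle_experiment(queries, refs, 0.03, 8, seed=17, matcher="greedy")
        assert [r.assignments for r in a.per_shuffle] == [
            r.assignments for r in b.per_shuffle
        ]


class TestMatcherMetrics:
    def test_observed_equals_truth(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        truth = exhaustive_assign(queries, refs, 0.03)
        assert matcher_metrics(truth, truth) == (1.0, 1.0)

    def test_assigning_nothing(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        truth = exhaustive_assign(queries, refs, 0.03)
        observed = ReferenceAssignment(
            {q: UNASSIGNED for q in queries.names}, 0.03
        )
        assert matcher_metrics(observed, truth) == (0.0, 1.0)

    def test_lax_matcher_against_hand_enumeration(self, rng):
        """A 0.05-threshold matcher scored against 0.03 truth."""
        refs = AlignedSequenceSet(
            [f"r{i}" for i in range(6)], random_sequences(rng, 6, 100)
        )
        queries = AlignedSequenceSet(
            [f"q{i}" for i in range(15)],
            [mutate(refs.sequences[i % 6], range(i % 7)) for i in range(15)],
        )
        truth = exhaustive_assign(queries, refs, 0.03)
        observed = exhaustive_assign(queries, refs, 0.05)
        sens, spec = matcher_metrics(observed, truth)
        pos = [q for q in queries.names if truth.assignments[q] != UNASSIGNED]
        neg = [q for q in queries.names if truth.assignments[q] == UNASSIGNED]
        hand_sens = sum(
            observed.assignments[q] != UNASSIGNED for q in pos
        ) / len(pos)
        hand_spec = sum(
            observed.assignments[q] == UNASSIGNED for q in neg
        ) / len(neg)
        assert (sens, spec) == (hand_sens, hand_spec)

    def test_query_set_mismatch_rejected(self, two_hit_fixture):
        queries, refs = two_hit_fixture
        truth = exhaustive_assign(queries, refs, 0.03)
        with pytest.raises(UsageError):
            matcher_metrics(ReferenceAssignment({"other": UNASSIGNED}, 0.03), truth)


class TestWithinOtuSpread:
    def test_disjoint_three_percent_queries_are_six_percent_apart(self):
        ref = "ACGT" * 25
        qa = mutate(ref, [0, 1, 2])
        qb = mutate(ref, [3, 4, 5])
        refs = AlignedSequenceSet(["ref"], [ref])
        queries = AlignedSequenceSet(["qa", "qb"], [qa, qb])
        out = exhaustive_assign(queries, refs, 0.03)
        assert out.matched_count == 2
        spread = within_otu_spread(out, queries)
        assert spread["ref"] == pytest.approx(0.06)

    def test_singleton_otu_is_zero(self, rng):
        refs = AlignedSequenceSet(["r"], random_sequences(rng, 1, 40))
        queries = AlignedSequenceSet(["q"], [refs.sequences[0]])
        out = exhaustive_assign(queries, refs, 0.03)
        assert within_otu_spread(out, queries) == {"r": 0.0}

    def test_matches_double_loop_oracle(self, rng):
        refs = AlignedSequenceSet(
            [f"r{i}" for i in range(4)], random_sequences(rng, 4, 80)
        )
        queries = AlignedSequenceSet(
            [f"q{i}" for i in range(16)],
            [mutate(refs.sequences[i % 4], range(i % 5)) for i in range(16)],
        )
        out = exhaustive_assign(queries, refs, 0.1)
        spread = within_otu_spread(out, queries)
        for ref in spread:
            members = [q for q, r in out.matched.items() if r == ref]
            expected = 0.0
            for a, b in itertools.combinations(members, 2):
                expected = max(
                    expected, pairwise_distance(queries.get(a), queries.get(b))
                )
            assert spread[ref] == pytest.approx(expected)

    def test_spread_bounded_by_twice_threshold(self, rng):
        """Hamming triangle inequality: spread <= 2t on ungapped queries."""
        for t in (0.03, 0.05, 0.10):
            refs = AlignedSequenceSet(
                [f"r{i}" for i in range(5)], random_sequences(rng, 5, 100)
            )
            queries = AlignedSequenceSet(
                [f"q{i}" for i in range(25)],
                [mutate(refs.sequences[i % 5], range(i % 11)) for i in range(25)],
            )
            out = exhaustive_assign(queries, refs, t)
            for value in within_otu_spread(out, queries).values():
                assert value <= 2 * t + 1e-12
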