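# Methods

## The assessment model

`otuqc` treats OTU quality as a binary-classification problem over
sequence pairs. Fix an evaluation threshold *t* (default 0.03, the
conventional species-level OTU radius). Each of the n(n−1)/2 unordered
pairs is "similar" when its observed dissimilarity is ≤ *t* (closed
interval: a pair at exactly 0.03 belongs inside a 3% OTU) and "together"
when the partition co-clusters it. TP/FN/FP/TN follow, and the Matthews
correlation coefficient condenses them. The numerator TP·TN − FP·FN and
the radicand (TP+FP)(TP+FN)(TN+FP)(TN+FN) are formed in Python's
arbitrary-precision integers before the single final division, so counts
on the order of 10¹² pairs lose no precision.

Zero-denominator convention (deliberately ours — upstream tools do not
document theirs): FP = FN = 0 scores 1.0, because a partition that makes
no pairing errors is perfect even when one margin is empty (the
all-singleton, all-distant community must not score 0); any other
vanishing marginal scores 0.0. A consequence used as a test invariant:
MCC = 1 exactly when FP = FN = 0. Undefined sensitivity or specificity
(empty denominator) is reported as 1.0 with a `*_defined = False` flag.

## Distances and gap policy

Dissimilarity is mismatches over compared columns between two equal-length
aligned sequences. The default policy mirrors the dominant convention in
amplicon distance calculators: columns where both sequences are gapped, or
that fall under a terminal gap of either sequence, or that contain an N,
are excluded; an internal run of consecutive gap columns counts as a
single difference over a single compared column. A second policy counts
every internal gap column individually. Which treatment "should" be used
is genuinely open, so both are provided and the policy is an explicit
argument everywhere; on gap-free sequences they coincide with the Hamming
fraction. U compares equal to T. A pair with zero comparable columns has
no defined distance and raises rather than returning a sentinel.

## Sparse distance storage

`DistanceMatrix` stores only pairs at or below an explicit
`storage_cutoff`; an absent pair means *distance > cutoff*, nothing more.
Every consumer either honours that semantics (absent ⇒ "distant" in
confusion counting, absent ⇒ `storage_cutoff + ε` in linkage averages,
with ε = 10⁻⁶) or refuses to run (`SparsityError`) when its own threshold
would need distances beyond the cutoff. A cutoff of 1.0 is dense and makes
the error impossible. Distances are carried at full float precision; the
on-disk formats emit 6 decimals.

## Clustering

Agglomerative merging of the current closest cluster pair while the
smallest inter-cluster distance is ≤ the cutoff. Inter-cluster distance:
minimum stored cross pair (nearest), maximum with any absent pair forcing
"unmergeable" (furthest), or the unweighted arithmetic mean over all cross
pairs with absent pairs contributing `storage_cutoff + ε` (average).
Whether historical implementations averaged over all pairs or over
size-weighted representatives is not something we assert; all-pairs UPGMA
is this package's documented choice.

Ties are broken by the lexicographically smallest pair of cluster
representatives, a cluster's representative being its smallest member
name. For disjoint clusters this equals the smallest sorted cross
name-pair, so the rule is content-derived: the merge sequence, and hence
every partition, is invariant under permutation of the input order. That
turns the stability experiment (30 randomized input orders) into a sharp
guarantee — the MCC range is exactly 0.0 — rather than an empirical
smallness claim.

Merge heights are reported on a rounded ladder: height *h* falls under
label ⌊h·precision + 0.5⌋ / precision (default precision 100, giving the
familiar 0.01/0.02/0.03 labels); consecutive merges sharing a label
collapse into one reported partition, and the ladder starts at "unique"
(all singletons). `partition_at` resolves a requested label to the largest
emitted label not exceeding it, the standard list-file convention.
Incremental linkage bookkeeping (count/min/max/sum per cluster pair) keeps
clustering O(n² log-ish) in practice; the test suite pins it to an O(n³)
from-scratch oracle and, for single linkage, to graph connected
components.

## Closed-reference matching

`exhaustive_assign` is best-hit: minimum-distance reference within the
threshold, distance ties to the lexicographically smallest reference name;
provably independent of query and database order, which is why it serves
as the operational ground truth for matcher sensitivity (fraction of
truly matchable queries assigned) and specificity (fraction of
unmatchable queries left unassigned). `greedy_assign` is first-hit in a
given database order — a deliberate model of the early-termination
heuristics that make production matchers database-order dependent, not an
emulation of any specific tool's k-mer screening. A query within the
threshold of several references is the minimal pathological unit:
`shuffle_experiment` runs seeded database permutations and reports the
matched-count range and whether assignment identity varied.

`within_otu_spread` reports, per reference OTU, the maximum pairwise
dissimilarity among the queries pooled into it. For ungapped equal-length
sequences the metric is a Hamming fraction and obeys the triangle
inequality, so the spread is bounded by twice the matching threshold; the
bound is attained by two queries diverging from the reference at disjoint
position sets — 6% inside a "97% similarity" OTU.

## The simulator

`generate_reference_pool` emulates a pool of sequences unique within a
hypervariable region: `n_clades` ancestors drawn uniformly over A/C/G/T,
each member copying an ancestor with per-position substitution to a
different base. Defaults, chosen once: alignment length 250 (V4-like
scale), mutation rate 0.01 per position (expected within-clade pairwise
dissimilarity ≈ 2 × 0.01, i.e. clades that cohere at the 3% threshold
without being degenerate), clade size ≈ 20 (`n_clades = round(n/20)`).
Duplicates are resampled; exhausting the retry budget (1000 per member,
reachable only in degenerate corners like length 1) raises.

Communities: even design assigns every member the same frequency (default
100 reads); staggered design draws abundances i.i.d. from the *discrete*
uniform distribution on the integers [low, high] (default 1..200 —
abundances are read counts, so a continuous-then-rounded reading was
rejected). `realize_reads` expands a profile into a seeded-shuffled read
list with replicate-suffixed names, the substrate for input-order
experiments. All randomness flows through `numpy.random.default_rng`;
in the CLI a single `--seed` fans out to per-stage seeds via
`SeedSequence`, so one flag reproduces a run.

What the simulator does *not* emulate: sequencing error, chimeras, PCR
bias, length variation, alignment uncertainty, or realistic phylogenetic
branch-length structure. Passing tests on simulated pools therefore
demonstrate the correctness and determinism of the machinery — exact
confusion counting, linkage semantics, order (in)variance — not that any
particular MCC value will be attained on real survey data, where
between-clade distances are far less separated than the ≈0.75 of random
ancestors.

## Problem sizes and numerics in the test suite

Randomized-oracle suites run at the scales where the oracles are exact
and fast: confusion counting on 500 instances up to n = 200; single
linkage vs connected components on 100 instances up to n = 50 (distances
drawn on a 1/1000 grid and labels kept at precision 10⁶ so label rounding
cannot straddle the query threshold); the three-method linkage oracle on
n ≤ 8 with distances on a 1/64 grid, which makes every sum exact in
binary floating point and exercises the tie rule heavily. The stability
guarantee is checked on a 500-sequence simulated community (storage
cutoff 0.10, cluster cutoff and threshold 0.03) with 30 shuffles per
method. Degenerate inputs are pinned by unit tests: single-pair matrices,
all-distant communities, empty threshold grids, zero-frequency profiles,
and the undefined-distance case.

## Known limitations

* Average-linkage values depend on the documented ε penalty for absent
  pairs; with very sparse matrices and cutoffs near the storage cutoff,
  a different ε convention would shift merge heights near the boundary.
* The greedy matcher is a minimal model of order dependence; it does not
  reproduce any specific tool's heuristic accept/reject schedule, so its
  sensitivity/specificity are illustrative, not predictions for a named
  tool.
* Distances require pre-aligned input; no aligner is included.
* The clusterer holds the sparse pair list in memory; it is sized for
  10⁴-sequence pools, not 10⁶-read raw datasets.
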