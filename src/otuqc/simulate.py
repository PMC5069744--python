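"""Synthetic reference pools and simulated amplicon communities.

The generator emulates the construction of benchmark data sets built by
sampling thousands of 16S rRNA sequences that are unique within a
hypervariable region (V4-like, ~250 bp): a configurable number of random
ancestor sequences ("clades") are each diversified by per-position
substitution, giving a pool of pairwise-distinct sequences whose mutual
dissimilarities span from well below to far above the conventional 3% OTU
threshold.  No database download is involved; the property that matters
downstream — a pool of unique, variably similar sequences — is preserved.

Two community designs are provided:

* even — every pool member at the same read frequency (default 100);
* staggered — abundances drawn from a discrete uniform distribution on
  the integers [low, high] (default 1..200), independently per member.

:func:`realize_reads` expands a profile into an ordered, seeded-shuffled
read list, the substrate for input-order randomization experiments.

All randomness flows through ``numpy.random.default_rng(seed)``, so every
generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FormatError, GenerationError, UsageError
from .seqio import AlignedSequenceSet, PathLike

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default pool alignment length, on the scale of the 16S V4 region.
DEFAULT_LENGTH = 250
#: Default per-position substitution rate away from the clade ancestor;
#: gives expected within-clade pairwise dissimilarity near 0.02, i.e.
#: clades that cohere at the 3% threshold without being trivial.
DEFAULT_MUTATION_RATE = 0.01
#: Default clade size used when n_clades is not given.
DEFAULT_CLADE_SIZE = 20

_RETRIES_PER_SEQUENCE = 1000


@dataclass(frozen=True)
class CommunityProfile:
    """Per-sequence read abundances for a simulated community."""

    abundances: dict[str, int]
    design: str  # "even" or "staggered"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.design not in ("even", "staggered"):
            raise UsageError(f"unknown design {self.design!r}")
        if not self.abundances:
            raise UsageError("empty community profile")
        values = list(self.abundances.values())
        if any(v < 1 for v in values):
            raise UsageError("every abundance must be >= 1")
        if self.design == "even" and len(set(values)) != 1:
            raise UsageError("even design requires equal abundances")

    @property
    def total_reads(self) -> int:
        return sum(self.abundances.values())


def generate_reference_pool(
    n: int,
    length: int = DEFAULT_LENGTH,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    n_clades: Optional[int] = None,
    seed: Optional[int] = None,
) -> AlignedSequenceSet:
    """Generate ``n`` pairwise-distinct, clade-structured sequences.

    ``n_clades`` random ancestors are drawn uniformly over A/C/G/T; each
    pool member copies an ancestor (members are spread evenly over clades)
    and substitutes each position with probability ``mutation_rate`` to a
    uniformly chosen *different* base.  Duplicates are resampled; if a
    member cannot be made unique within the retry budget a
    :class:`~otuqc.errors.GenerationError` is raised (this happens only in
    degenerate corners such as length 1).
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    if length < 1:
        raise UsageError("length must be >= 1")
    if not 0.0 < mutation_rate < 1.0:
        raise UsageError("mutation_rate must lie strictly between 0 and 1")
    if n_clades is None:
        n_clades = max(1, round(n / DEFAULT_CLADE_SIZE))
    if not 1 <= n_clades <= n:
        raise UsageError("n_clades must lie in [1, n]")

    rng = np.random.default_rng(seed)
    ancestors = rng.integers(0, 4, size=(n_clades, length), dtype=np.uint8)

    seen: set[bytes] = set()
    names: list[str] = []
    sequences: list[str] = []
    width = max(5, len(str(n)))
    for i in range(n):
        ancestor = ancestors[i % n_clades]
        for _ in range(_RETRIES_PER_SEQUENCE):
            member = ancestor.copy()
            mask = rng.random(length) < mutation_rate
            k = int(mask.sum())
            if k:
                member[mask] = (member[mask] + rng.integers(1, 4, size=k)) % 4
            key = member.tobytes()
            if key not in seen:
                seen.add(key)
                names.append(f"seq{i + 1:0{width}d}")
                sequences.append(_BASES[member].tobytes().decode("ascii"))
                break
        else:
            raise GenerationError(
                f"could not generate {n} unique sequences of length {length} "
                f"at mutation rate {mutation_rate}"
            )
    return AlignedSequenceSet(names, sequences)


def even_community(pool: AlignedSequenceSet, frequency: int = 100) -> CommunityProfile:
    """Every pool member at the same read frequency (default 100)."""
    if frequency < 1:
        raise UsageError("frequency must be >= 1")
    return CommunityProfile({name: frequency for name in pool.names}, "even")


def staggered_community(
    pool: AlignedSequenceSet,
    low: int = 1,
    high: int = 200,
    seed: Optional[int] = None,
) -> CommunityProfile:
    """Abundances drawn i.i.d. from discrete uniform on [low, high]."""
    if low < 1:
        raise UsageError("low must be >= 1")
    if low > high:
        raise UsageError("low must not exceed high")
    rng = np.random.default_rng(seed)
    draws = rng.integers(low, high + 1, size=len(pool.names))
    design = "even" if low == high else "staggered"
    return CommunityProfile(
        {name: int(a) for name, a in zip(pool.names, draws)}, design, seed
    )


def realize_reads(
    profile: CommunityProfile,
    pool: AlignedSequenceSet,
    seed: Optional[int] = None,
) -> list[str]:
    """Expand a profile into a seeded-shuffled ordered read list.

    Each sequence name is emitted once per read, suffixed ``_<replicate>``
    to keep read names unique, then the whole list gets one seeded
    permutation.  The multiset of base names always equals the profile.
    """
    unknown = set(profile.abundances) - set(pool.names)
    if unknown:
        raise UsageError(f"profile names absent from pool: {sorted(unknown)[:3]}")
    reads = [
        f"{name}_{k + 1}"
        for name in pool.names
        if name in profile.abundances
        for k in range(profile.abundances[name])
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def read_source(read_name: str) -> str:
    """Base pool-sequence name of a read emitted by :func:`realize_reads`."""
    return read_name.rsplit("_", 1)[0]


def write_profile(profile: CommunityProfile, path: PathLike) -> None:
    """Write a two-column tab-separated (name, reads) profile."""
    with open(path, "w") as fh:
        for name, reads in profile.abundances.items():
            fh.write(f"{name}\t{reads}\n")


def read_profile(path: PathLike, design: str = "staggered") -> CommunityProfile:
    """Read a two-column tab-separated (name, reads) profile."""
    abundances: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'name reads'")
            name, raw = parts
            try:
                reads = int(raw)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad read count {raw!r}") from None
            if name in abundances:
                raise FormatError(f"{path}:{lineno}: duplicate name {name!r}")
            abundances[name] = reads
    if not abundances:
        raise FormatError(f"{path}: empty profile")
    values = set(abundances.values())
    if design == "even" and len(values) != 1:
        design = "staggered"
    return CommunityProfile(abundances, design)
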