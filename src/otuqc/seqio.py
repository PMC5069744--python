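"""Reading and writing aligned FASTA and pairwise-distance files.

Three on-disk dialects are supported:

* aligned FASTA (via Biopython), where every record must share one
  alignment length;
* the "column" pair-list distance dialect: one whitespace-separated
  ``nameA nameB distance`` triple per line, no header;
* PHYLIP lower-triangle distance matrices (read only): a count line, then
  one name per row followed by that row's lower-triangle distances
  (wrapped lines are tolerated — parsing is token-driven).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distance import DistanceMatrix, _pair_key
from .errors import AlignmentError, FormatError

_ALLOWED = frozenset("ACGTUN-.")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Named, equal-length gapped sequences — the clustering substrate.

    Order is significant: downstream operations that probe input-order
    dependence permute it deliberately.
    """

    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.names:
            raise FormatError("empty sequence set")
        if len(self.names) != len(self.sequences):
            raise FormatError("names and sequences differ in count")
        if len(set(self.names)) != len(self.names):
            dup = sorted({n for n in self.names if self.names.count(n) > 1})
            raise FormatError(f"duplicate sequence identifier(s): {dup[:3]}")
        length = len(self.sequences[0])
        for name, seq in zip(self.names, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence {name!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq.upper()) - _ALLOWED
            if bad:
                raise FormatError(
                    f"sequence {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.names)

    def get(self, name: str) -> str:
        return self.sequences[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "AlignedSequenceSet":
        by_name = dict(zip(self.names, self.sequences))
        return AlignedSequenceSet(list(names), [by_name[n] for n in names])

    def reorder(self, names: Sequence[str]) -> "AlignedSequenceSet":
        if set(names) != set(self.names) or len(names) != len(self.names):
            raise FormatError("reorder requires a permutation of the names")
        return self.subset(names)


def read_fasta(path: PathLike) -> AlignedSequenceSet:
    """Read an aligned FASTA file, preserving record order.

    The identifier is the header token up to the first whitespace.
    """
    names: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        names.append(record.id)
        seqs.append(str(record.seq))
    if not names:
        raise FormatError(f"no FASTA records in {path}")
    return AlignedSequenceSet(names, seqs)


def write_fasta(seqs: AlignedSequenceSet, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=n, description="")
        for n, s in zip(seqs.names, seqs.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_column_distances(matrix: DistanceMatrix, path: PathLike) -> None:
    """Write the pair-list dialect: ``nameA nameB distance``, 6 decimals."""
    with open(path, "w") as fh:
        for (a, b), d in sorted(matrix.entries.items()):
            fh.write(f"{a}\t{b}\t{d:.6f}\n")


def read_column_distances(
    path: PathLike,
    names: Optional[Sequence[str]] = None,
    storage_cutoff: float = 1.0,
) -> DistanceMatrix:
    """Read the pair-list dialect.

    If ``names`` is given it fixes the matrix name universe and any name in
    the file outside it is a format error; otherwise names are inferred
    from the file in order of first appearance (note that a sparse file
    cannot mention sequences with no stored pairs).
    """
    known = set(names) if names is not None else None
    seen: list[str] = []
    seen_set: set[str] = set()
    entries: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'nameA nameB distance'")
            a, b, raw = parts
            try:
                d = float(raw)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad distance {raw!r}") from None
            if not 0.0 <= d <= 1.0:
                raise FormatError(f"{path}:{lineno}: distance {d} outside [0, 1]")
            if a == b:
                raise FormatError(f"{path}:{lineno}: self pair {a!r}")
            for name in (a, b):
                if known is not None and name not in known:
                    raise FormatError(f"{path}:{lineno}: unknown name {name!r}")
                if name not in seen_set:
                    seen.append(name)
                    seen_set.add(name)
            entries[_pair_key(a, b)] = d
    final_names = list(names) if names is not None else seen
    return DistanceMatrix(final_names, storage_cutoff, entries)


def read_phylip_lower(path: PathLike) -> DistanceMatrix:
    """Read a PHYLIP lower-triangle distance matrix as a dense matrix.

    Row *i* (0-based) holds a name followed by *i* distances.  Line wraps
    inside a row are tolerated; a token count that disagrees with the
    header is a format error.
    """
    text = Path(path).read_text()
    tokens = text.split()
    if not tokens:
        raise FormatError(f"{path}: empty file")
    try:
        count = int(tokens[0])
    except ValueError:
        raise FormatError(f"{path}: first token must be the sequence count") from None
    if count < 1:
        raise FormatError(f"{path}: sequence count must be >= 1")
    expected = count + count * (count - 1) // 2
    body = tokens[1:]
    if len(body) != expected:
        raise FormatError(
            f"{path}: header declares {count} taxa ({expected} tokens) "
            f"but found {len(body)}"
        )
    names: list[str] = []
    entries: dict[tuple[str, str], float] = {}
    pos = 0
    for i in range(count):
        name = body[pos]
        pos += 1
        row: list[float] = []
        for j in range(i):
            try:
                d = float(body[pos])
            except ValueError:
                raise FormatError(
                    f"{path}: bad distance {body[pos]!r} in row for {name!r}"
                ) from None
            if not 0.0 <= d <= 1.0:
                raise FormatError(f"{path}: distance {d} outside [0, 1]")
            row.append(d)
            pos += 1
        if name in names:
            raise FormatError(f"{path}: duplicate taxon {name!r}")
        for j, d in enumerate(row):
            entries[_pair_key(names[j], name)] = d
        names.append(name)
    return DistanceMatrix(names, 1.0, entries)
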