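"""Exception hierarchy for otuqc.

All library errors derive from :class:`OtuqcError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class OtuqcError(Exception):
    """Base class for all otuqc errors."""


class FormatError(OtuqcError):
    """Malformed input file (FASTA, distance, list, or profile dialect)."""


class AlignmentError(OtuqcError):
    """Sequences that must share an alignment length do not."""


class UndefinedDistanceError(OtuqcError):
    """A pairwise distance has zero compared columns under the gap policy."""


class SparsityError(OtuqcError):
    """An operation needs pairs beyond the matrix storage cutoff."""


class GenerationError(OtuqcError):
    """The simulator could not satisfy its contract (e.g. uniqueness)."""


class UsageError(OtuqcError):
    """Invalid argument combination or out-of-range parameter."""
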