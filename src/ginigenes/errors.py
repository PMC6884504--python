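"""Exception hierarchy shared across the package.

All data-quality problems raise a subclass of :class:`GiniGenesError`, so
callers can catch one base class at pipeline boundaries while tests can
assert on the precise failure mode.
"""


class GiniGenesError(Exception):
    """Base class for all package-specific errors."""


class MalformedDataError(GiniGenesError):
    """A value in an input file violates the format contract (negative
    abundance, non-numeric cell, comma decimal separator, ...). The message
    names the offending row and column."""


class DuplicateGeneError(GiniGenesError):
    """Duplicate gene identifiers encountered under the ``reject`` policy."""


class DegenerateSampleError(GiniGenesError):
    """A sample column sums to zero and cannot be renormalised."""


class UndefinedStatisticError(GiniGenesError):
    """A statistic is mathematically undefined for the given input
    (e.g. the Gini coefficient of an all-zero vector)."""


class InsufficientDataError(GiniGenesError):
    """Fewer observations than the operation's stated minimum."""


class VocabularyError(GiniGenesError):
    """A label outside a closed controlled vocabulary."""
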