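"""Exception hierarchy for deafscape.

All package-specific failures derive from :class:`DeafscapeError` so callers
can catch the whole family; the leaves distinguish configuration problems,
missing inputs, and statistics that are undefined for the given counts.
"""


class DeafscapeError(Exception):
    """Base class for all deafscape errors."""


class InvalidConfigError(DeafscapeError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(DeafscapeError, ValueError):
    """An input value is outside the operation's domain."""


class UnknownDialectError(DeafscapeError, KeyError):
    """A pathogenicity source is not in the label-dialect registry."""


class MissingDataError(DeafscapeError):
    """A required piece of data (label map, CDS sequence, ...) is absent."""


class OutOfScopeError(DeafscapeError):
    """A variant falls outside the transcript's annotatable window."""


class UndefinedStatisticError(DeafscapeError):
    """A 2x2-table statistic is undefined (an empty stratum)."""


class UnstableEstimateError(DeafscapeError):
    """Too many bootstrap resamples were degenerate to trust the interval."""


class InsufficientDataError(DeafscapeError):
    """Not enough observations to compute the requested quantity."""


class DegenerateFitError(DeafscapeError):
    """A regression cannot be fitted (e.g. constant predictor)."""


class ZeroVarianceError(DeafscapeError):
    """A profile with zero variance cannot be z-scored."""


class ConsistencyError(DeafscapeError):
    """Two objects that must correspond (models vs partition) do not."""
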