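"""Exception hierarchy.

Every error the package raises derives from :class:`TlsegError`, so callers
(notably the CLI) can distinguish domain failures from genuine bugs.
"""


class TlsegError(Exception):
    """Base class for all package errors."""


class FormatError(TlsegError):
    """File is not a readable volume container."""


class DimensionalityError(TlsegError):
    """Image data is not three-dimensional."""


class BoundsError(TlsegError):
    """A region of interest does not fit inside its volume."""


class ParameterError(TlsegError):
    """A parameter violates its documented constraint."""


class NumericError(TlsegError):
    """Non-finite values where finite ones are required."""


class DegenerateInterfaceError(TlsegError):
    """Level-set field or mask has only one phase (no interface)."""


class DegenerateStatisticsError(TlsegError):
    """Region statistics are undefined (empty region, zero denominator)."""


class AssumptionViolationError(TlsegError):
    """The bright-foreground model assumption mu_a > mu_b is violated."""


class SeedRejectedError(TlsegError):
    """Region-growing seed lies outside the admissible intensity range."""


class EvolutionCollapseError(TlsegError):
    """A level-set evolution collapsed to an empty or full mask."""


class UndefinedMetricError(TlsegError):
    """A validation metric is undefined for the given mask pair."""


class AlignmentError(TlsegError):
    """Two grids that must be aligned have different shapes."""
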