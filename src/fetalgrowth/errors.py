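"""Exception hierarchy.

Every error raised by this package derives from :class:`FetalGrowthError`
so callers can catch the whole family with one clause.
"""


class FetalGrowthError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FetalGrowthError, ValueError):
    """An argument violates an operation's precondition."""


class SingularDesignError(FetalGrowthError):
    """The Gram matrix of the design is rank deficient (e.g. a single
    duplicated age); ordinary least squares has no unique solution.
    Ridge regression (``lam > 0``) regularizes this case."""


class UndefinedStatisticError(FetalGrowthError):
    """A statistic is undefined for the given data (zero total sum of
    squares, zero residual degrees of freedom, all-tied ranks, ...)."""


class RangeError(FetalGrowthError, ValueError):
    """A gestational age lies outside a model's fitted range and
    extrapolation was not requested."""


class GenerationError(FetalGrowthError):
    """The synthetic cohort generator could not satisfy a constraint
    (positivity resampling exhausted its retry budget)."""


class InsufficientDataError(FetalGrowthError):
    """Too few observations for the requested computation."""


class InvalidStateError(FetalGrowthError):
    """An object is missing state required by the operation
    (e.g. reference-band construction without coefficient SEs)."""


class ParseError(FetalGrowthError, ValueError):
    """A records file failed validation; the message cites the row."""
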