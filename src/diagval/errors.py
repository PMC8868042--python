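"""Exception hierarchy.

Every error raised on invalid scientific input derives from DiagvalError,
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class DiagvalError(ValueError):
    """Base class for all domain errors."""


class NoRecordsError(DiagvalError):
    """An empty record sequence was offered where at least one unit is required."""


class DuplicateUnitError(DiagvalError):
    """Two records share the same (unit_id, side) pair."""


class InconsistentSummaryError(DiagvalError):
    """No integer 2x2 table is compatible with the printed rounded summaries."""


class NotIdentifiableError(DiagvalError):
    """The imperfect-reference correction's denominator is non-positive."""


class UndefinedStatisticError(DiagvalError):
    """A statistic's denominator is zero (or kappa's chance agreement is 1)."""


class DegenerateIntervalError(DiagvalError):
    """A likelihood-ratio interval cannot be formed (zero cell or undefined ratio)."""
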