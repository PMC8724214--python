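"""Exception hierarchy for fapindex."""


class FapindexError(Exception):
    """Base class for all package errors."""


class FormatError(FapindexError):
    """A peak table / library / calibration file does not match the documented schema."""


class EmptyInputError(FapindexError):
    """An input file or table contains no usable records."""


class MissingAnchorError(FapindexError):
    """Fewer FAP peaks than expected anchor carbons; names the missing carbons."""

    def __init__(self, message: str, missing_carbons=()):
        super().__init__(message)
        self.missing_carbons = tuple(missing_carbons)


class AnchorConsistencyError(FapindexError):
    """Anchor assignment would violate monotonicity."""


class OutOfLadderError(FapindexError):
    """Retention time / index outside the anchor ladder.

    Carries a hint (e.g. to include the 26:0 pyrrolidide for unexpectedly
    late-eluting analytes).
    """

    def __init__(self, message: str, hint: str | None = None):
        super().__init__(message if hint is None else f"{message} ({hint})")
        self.hint = hint


class AnchorGapError(FapindexError):
    """The anchor ladder has a gap spanning the requested time/index."""


class CalibrationError(FapindexError):
    """Invalid retention-time-locking calibration input."""


class ExtrapolationError(FapindexError):
    """Lock target outside the retention-time range spanned by the calibration."""


class RuleGapError(FapindexError):
    """A sterol descriptor cannot be mapped to diagnostic-ion rules."""

    def __init__(self, message: str, missing_attributes=()):
        super().__init__(message)
        self.missing_attributes = tuple(missing_attributes)


class LibraryConsistencyError(FapindexError):
    """Library molecular ion inconsistent with the computed TMS mass."""


class SchedulingError(FapindexError):
    """A SIM time window cannot satisfy the ion budget."""


class UndefinedCompositionError(FapindexError):
    """Composition requested for a run with zero total annotated area."""


class GenerationError(FapindexError):
    """Synthetic run generation failed (e.g. compound outside anchor range)."""
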