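"""Exception types shared across the pipelines."""


class TwistSpacerError(Exception):
    """Base class for package-specific errors."""


class InvalidSequenceError(TwistSpacerError, ValueError):
    """A nucleotide sequence is empty, too short, or contains non-ACGT letters."""


class MissingReferenceError(TwistSpacerError, ValueError):
    """A dataset lacks the reference-spacer measurement required for normalization."""


class InsufficientDataError(TwistSpacerError, ValueError):
    """Too few data points (or an empty group) for the requested statistic."""


class UndefinedRatioError(TwistSpacerError, ZeroDivisionError):
    """A fold-change denominator is zero."""


class OutOfRangeError(TwistSpacerError, ValueError):
    """A requested evaluation time falls outside the recorded series."""


class PromoterMapFormatError(TwistSpacerError, ValueError):
    """A promoter-map table is missing required columns or is unparseable."""
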