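"""Exception hierarchy.

All package errors derive from :class:`AffectFlexError` so callers can
distinguish validation problems (exit code 2 in the CLI) from data-quality
aborts (exit code 3).
"""


class AffectFlexError(Exception):
    """Base class for all affectflex errors."""


class InvalidParameterError(AffectFlexError, ValueError):
    """A parameter violates its documented domain."""


class SamplingRateError(InvalidParameterError):
    """Sampling rate too low for the requested operation."""


class InsufficientDataError(AffectFlexError, ValueError):
    """Input too short for the operation's preconditions."""


class EmptyInputError(InsufficientDataError):
    """Empty signal or series where data is required."""


class NoBeatsError(AffectFlexError):
    """Beat detection found no beats (flat or ineffective acquisition)."""


class QualityError(AffectFlexError):
    """Recording failed quality control (too many artifacts) and is unusable."""


class PoolExhaustedError(AffectFlexError):
    """An image pool cannot supply enough stimuli for a quadrant."""


class DesignError(AffectFlexError, ValueError):
    """Statistical design invalid (group too small, missing cell, ...)."""


class DegenerateInputError(AffectFlexError, ValueError):
    """Constant or zero-variance input where variability is required."""


class MissingDataError(AffectFlexError, ValueError):
    """Missing values present and listwise deletion not enabled."""


class ConfigError(AffectFlexError, ValueError):
    """Invalid or incomplete run configuration."""
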