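"""Exception hierarchy for the cardiotrait pipeline."""


class CardioTraitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CardioTraitError):
    """A required configuration value is missing or inconsistent."""


class LoadError(CardioTraitError):
    """An input file could not be parsed into a valid record or table."""


class ParameterError(CardioTraitError, ValueError):
    """An argument violates the documented preconditions of an operation."""


class StructuralError(CardioTraitError):
    """A feature table or vector does not have the expected structure."""


class InsufficientDataError(CardioTraitError):
    """Too few samples, beats or intervals to compute the requested statistic."""


class SignalTooShortError(InsufficientDataError):
    """Record shorter than the filter warm-up period."""


class DetectionError(CardioTraitError):
    """No beats could be detected in the record."""


class DelineationQualityError(CardioTraitError):
    """Too many beats were dropped during wave delineation."""


class DegenerateLabelsError(CardioTraitError):
    """A training set contains a single class; classification is undefined."""


class NotFittedError(CardioTraitError):
    """The model has not been trained yet."""


class UndefinedCorrelationError(CardioTraitError):
    """Rank correlation is undefined (constant input)."""
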