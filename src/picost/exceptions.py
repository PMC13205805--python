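"""Exception hierarchy for picost."""


class PicostError(Exception):
    """Base class for all picost errors."""


class ValidationError(PicostError, ValueError):
    """A data value violates a model invariant (negative area, duplicate id, ...)."""


class SchemaError(ValidationError):
    """An input file is missing a required column or has an unusable layout."""


class GenerationError(PicostError, RuntimeError):
    """The synthetic-cohort generator cannot satisfy its constraints."""


class EstimationError(PicostError, RuntimeError):
    """A statistical quantity cannot be estimated from the given data."""


class UndefinedRatioError(EstimationError):
    """The healing-acceleration ratio is undefined (zero denominator)."""


class DependencyError(PicostError, RuntimeError):
    """A requested output needs an upstream result that was not supplied."""


class ConfigurationError(PicostError, ValueError):
    """A configuration table or parameter set is incomplete or inconsistent."""


class PolarityWarning(UserWarning):
    """A ratio was formed over a negative denominator; its sign is inverted."""
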