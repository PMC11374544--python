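"""Exception and warning hierarchy shared by every pipeline stage."""


class PlateWasteError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PlateWasteError):
    """An input table is missing a required column or has a malformed cell."""


class IntegrityError(PlateWasteError):
    """A cross-reference (dish -> category, recipe -> composition, item -> factor)
    does not resolve."""


class ValidationError(PlateWasteError):
    """A value violates a domain invariant (negative mass, zero children, ...)."""


class ConfigurationError(PlateWasteError):
    """Campaign configuration is inconsistent with the data or the factor tables."""


class UndefinedRatioError(PlateWasteError):
    """A ratio was requested with a zero denominator."""


class DegenerateSampleError(PlateWasteError):
    """A statistical routine received a sample with no variability."""


class DataQualityWarning(UserWarning):
    """Emitted when a physically impossible value is floored or flagged
    (e.g. waste exceeding the served amount) instead of raising."""
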