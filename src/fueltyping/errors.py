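"""Exception hierarchy shared across the package."""


class FuelTypingError(Exception):
    """Base class for all package errors."""


class SchemaError(FuelTypingError):
    """A required column or attribute is missing from an input table."""


class ValidationError(FuelTypingError):
    """A record value violates its documented range or consistency rule."""


class LabelError(FuelTypingError, KeyError):
    """An unknown fuel-type code was supplied."""


class RangeError(FuelTypingError, ValueError):
    """A numeric argument lies outside its documented domain."""


class ExtentError(FuelTypingError):
    """A sample point falls outside a grid's extent."""


class GeometryError(FuelTypingError):
    """A polygon ring is degenerate or otherwise invalid."""


class TotalityError(FuelTypingError):
    """A rule set without a fallback fails to cover attribute space."""


class PairingError(FuelTypingError):
    """Two vectors that must be paired have different lengths."""


class ConfigurationError(FuelTypingError):
    """A configuration value is inconsistent or unreachable."""


class TraitError(FuelTypingError, KeyError):
    """A fuel-type code is absent from the trait table."""


class DegenerateInputError(FuelTypingError, ValueError):
    """A statistical routine received an input it cannot operate on."""


class DesignError(FuelTypingError):
    """A survey design is empty or internally inconsistent."""
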