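"""Exception hierarchy shared across the cryptax modules."""


class CryptaxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CryptaxError, ValueError):
    """Invalid parameters or malformed input data."""


class SchemaError(ValidationError):
    """A table does not match the expected column schema."""


class DomainError(ValidationError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateVarianceError(CryptaxError, ArithmeticError):
    """All groups have zero within-group variance; test statistic undefined."""


class InsufficientDataError(ValidationError):
    """Too few specimens/groups for the requested analysis."""


class UndefinedDistanceError(CryptaxError, ArithmeticError):
    """No comparable sites between two sequences."""


class SaturationError(CryptaxError, ArithmeticError):
    """Substitution saturation: the distance correction is undefined."""


class TPSFormatError(ValidationError):
    """Malformed TPS landmark file."""
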