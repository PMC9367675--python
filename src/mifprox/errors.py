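"""Exception hierarchy shared across the package."""


class MifproxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MifproxError, ValueError):
    """A required column/role is missing or mis-mapped in an input table."""


class RowParseError(MifproxError, ValueError):
    """A row-level value could not be parsed; the message cites the row index."""


class TableValidationError(MifproxError, ValueError):
    """A table violates an invariant (duplicate ids, non-finite coordinates, ...)."""


class ConfigurationError(MifproxError, ValueError):
    """Analysis/panel configuration is inconsistent or incomplete."""


class DegenerateInputError(MifproxError, ValueError):
    """An operation received an empty/insufficient point set where one is required."""


class DomainError(MifproxError, ValueError):
    """A numeric parameter lies outside the mathematical domain of a formula."""
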