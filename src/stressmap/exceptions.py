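"""Exception hierarchy shared across the package."""


class StressmapError(Exception):
    """Base class for all package errors."""


class FormatError(StressmapError):
    """A file does not conform to its declared dialect."""


class ValidationError(StressmapError):
    """Parsed content violates a domain invariant (vocabulary, range, order)."""


class UnusableTrackError(StressmapError):
    """A GPS track carries no usable time information."""


class TooShortError(StressmapError):
    """A signal is too short for the requested operation."""


class ContractError(StressmapError):
    """A precondition of an operation was violated by the caller."""


class InsufficientCellsError(StressmapError):
    """Fewer than two grid cells carry data; Gi* is undefined."""


class UndefinedChangeError(StressmapError):
    """Percent change is undefined because the baseline statistic is zero."""


class ConfigError(StressmapError):
    """A configuration value is inconsistent or out of range."""
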