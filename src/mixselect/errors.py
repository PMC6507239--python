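"""Exception hierarchy for mixselect."""


class MixselectError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MixselectError):
    """A configuration value is invalid or inconsistent."""


class InputError(MixselectError):
    """Required input (column, file, metadata) is absent."""


class ParseError(MixselectError):
    """A data file contains a cell that cannot be interpreted."""


class DomainError(MixselectError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateDataError(MixselectError):
    """Data carries no usable signal (constant outcome, zero-variance column,
    or every column filtered away)."""
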