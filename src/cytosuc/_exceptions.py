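"""Exception hierarchy.

Exit-code mapping used by the CLI:
0 success, 2 configuration error, 3 data error, 4 numerical error.
"""


class CytosucError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(CytosucError):
    """Invalid panel, model spec, or simulation configuration."""

    exit_code = 2


class DataError(CytosucError):
    """The data violate a precondition (state, shape, degeneracy)."""

    exit_code = 3


class ParseError(DataError):
    """A file could not be parsed into an event table."""


class StateError(DataError):
    """An operation was called on a table in the wrong transform state."""


class DegenerateDataError(DataError):
    """Zero-variance channel, constant vector, unimodal density, ..."""


class StratumSizeError(DataError):
    """A per-sample fit stratum holds too few cells."""


class NumericalError(CytosucError):
    """A numerical procedure failed."""

    exit_code = 4


class SingularDesignError(NumericalError):
    """The regression design matrix is rank deficient."""
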