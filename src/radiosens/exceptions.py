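"""Exception hierarchy.

Errors are split by how a pipeline should react: bad caller arguments
(:class:`ParameterError`), malformed or impossible input data
(:class:`DataError` and subclasses), and numerical/fitting failures
(:class:`FitError`).  The CLI maps these onto exit codes 1, 2 and 3.
"""


class RadiosensError(Exception):
    """Base class for all package errors."""


class ParameterError(RadiosensError, ValueError):
    """Invalid argument or configuration value."""


class DataError(RadiosensError, ValueError):
    """Input data violate a physical or logical constraint."""


class DataFormatError(DataError):
    """A file does not follow the documented column dialect."""


class CohortValidationError(DataError):
    """A cell-line record violates a type invariant."""


class MissingDataError(DataError):
    """A required measurement is absent."""


class InsufficientDataError(DataError):
    """Too few records/points for the requested analysis."""


class DegenerateDataError(DataError):
    """Data carry no usable variation (e.g. all values identical)."""


class DomainError(DataError):
    """Value outside the mathematical domain of a closed form."""


class FitError(RadiosensError, RuntimeError):
    """Numerical failure of a least-squares fit."""
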