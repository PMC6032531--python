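"""Exception hierarchy.

Two broad families matter for the CLI exit-code contract: configuration
problems (exit code 2) and data problems (exit code 3).
"""


class TgsigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TgsigError, ValueError):
    """An invalid parameter or configuration value (CLI exit code 2)."""


class DataError(TgsigError, ValueError):
    """Invalid or degenerate input data (CLI exit code 3)."""


class DegenerateInputError(DataError):
    """Input data carries no usable variation (e.g. constant variances)."""


class InsufficientReplicationError(DataError):
    """A group has too few samples for variance estimation."""


class MissingGeneError(DataError, KeyError):
    """A required gene is absent from a matrix or record table."""


class MissingRecordError(DataError, KeyError):
    """A gene lacks its differential-expression record."""


class MissingReferenceError(DataError):
    """A sample lacks Ct measurements for the reference gene."""


class SingleClassError(DataError):
    """An operation requiring both response classes saw only one."""


class AlignmentError(DataError):
    """Two inputs that must share a sample or gene set do not."""


class EmptyInputError(DataError):
    """An input that must be non-empty is empty."""


class PipelineHaltError(TgsigError, RuntimeError):
    """The discovery pipeline cannot proceed; carries the attrition report."""

    def __init__(self, message: str, attrition: dict | None = None):
        super().__init__(message)
        self.attrition = dict(attrition or {})
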