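"""Exception hierarchy shared across the package.

Validation errors (bad parameters, malformed configuration) and data errors
(malformed or inconsistent input files) are kept distinct so the command-line
layer can map them to different exit codes.
"""


class FamsegError(Exception):
    """Base class for all package errors."""


class ValidationError(FamsegError):
    """A parameter or configuration value is outside its documented range."""


class ConfigurationError(ValidationError):
    """An inconsistent combination of options (unknown panel, bad thresholds...)."""


class DataError(FamsegError):
    """Input data is malformed or internally inconsistent."""


class PedParseError(DataError):
    """A pedigree file row could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InconsistencyError(DataError):
    """Mendelian or structural contradiction (e.g. an individual forced to be
    both carrier and non-carrier)."""
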