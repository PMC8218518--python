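"""Exception hierarchy for the eSNV signature pipeline.

Every error raised deliberately by this package derives from
:class:`EsnvSigError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class EsnvSigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EsnvSigError, ValueError):
    """A parameter or configuration value is outside its valid range."""


class SimulationError(EsnvSigError):
    """The synthetic cohort could not be generated as requested."""


class DataError(EsnvSigError):
    """Input data are internally inconsistent (e.g. REF base mismatch)."""


class ParseError(EsnvSigError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class UndefinedTMBError(EsnvSigError, ZeroDivisionError):
    """TMB is undefined because the capture region is empty.

    A sample with zero capture bases should have been excluded upstream by
    the minimum-capture rule; reaching this error indicates a pipeline
    misconfiguration rather than a property of the data.
    """


class InsufficientDataError(EsnvSigError, ValueError):
    """Too few observations for the requested statistical operation."""


class AmbiguousContextError(EsnvSigError):
    """A trinucleotide context cannot be resolved (N base or missing flank)."""
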