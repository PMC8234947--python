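"""Exception hierarchy shared across the package."""


class ClustmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClustmrError):
    """Invalid configuration: missing columns, unknown policy strings, bad paths."""


class TableValidationError(ClustmrError):
    """One or more data rows failed validation.

    ``errors`` holds ``(row_number, message)`` pairs, row numbers 1-based over
    data rows (the header is row 0).
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors)
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}")


class ParameterError(ClustmrError):
    """A numeric argument is outside its admissible range."""


class NotEstimableError(ClustmrError):
    """The requested quantity cannot be estimated from the given inputs."""


class PipelineError(ClustmrError):
    """A pipeline stage failed; the message names the stage."""
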