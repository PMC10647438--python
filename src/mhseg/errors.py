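"""Exception hierarchy shared across the package."""


class MhsegError(Exception):
    """Base class for all package errors."""


class ValidationError(MhsegError, ValueError):
    """An input violated a documented precondition or invariant.

    ``field`` names the offending parameter when known.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message if field is None else f"{field}: {message}")


class GridMismatchError(ValidationError):
    """Volumes expected on a common grid differ in shape or spacing."""


class ConfigurationError(MhsegError, ValueError):
    """A run/model configuration is internally inconsistent."""


class SamplingError(MhsegError, RuntimeError):
    """Patch sampling could not satisfy its constraints."""


class TrainingDivergedError(MhsegError, RuntimeError):
    """The optimization loop produced a non-finite loss."""


class FormatError(MhsegError, IOError):
    """A file could not be parsed as the expected format."""
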