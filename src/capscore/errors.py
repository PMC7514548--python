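"""Exception types raised across the pipeline."""


class CapscoreError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedRateError(CapscoreError, ValueError):
    """Sampling rate below 100 Hz; upsampling is not supported."""


class DegenerateSignalError(CapscoreError, ValueError):
    """Constant (zero-variance) signal cannot be normalized."""


class EmptyTensorError(CapscoreError, ValueError):
    """Recording too short to yield a single one-second epoch."""


class DegenerateLabelError(CapscoreError, ValueError):
    """Training labels contain a single class."""


class NotTrainedError(CapscoreError, RuntimeError):
    """Prediction requested from an untrained model."""


class ProtocolViolationError(CapscoreError, ValueError):
    """A subject appears in both the training and the testing side."""


class AnnotationParseError(CapscoreError, ValueError):
    """Malformed annotation line; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
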