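"""Exception types shared across the pipeline.

Empty-result conditions get dedicated exceptions so the orchestrator can halt
with a report naming the stage instead of propagating a bare KeyError.
"""


class NetpharmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NetpharmError):
    """Invalid configuration value (bad range, unknown source, missing threshold)."""


class InputFormatError(NetpharmError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyNetworkError(NetpharmError):
    """A network construction or screening stage produced no surviving nodes."""


class NoModuleError(NetpharmError):
    """MCODE found no complex to report as the key module."""
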