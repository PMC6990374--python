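"""Package-wide exception types."""


class InfarctSimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(InfarctSimError):
    """Invalid configuration value or inconsistent geometry specification."""


class IntegrationError(InfarctSimError):
    """Numerical integration produced a non-finite or unstable state."""


class NoCaptureError(InfarctSimError):
    """A pacing stimulus failed to elicit an action potential."""

    def __init__(self, message: str, beat: int | None = None):
        super().__init__(message)
        self.beat = beat


class ProtocolError(InfarctSimError):
    """A pacing protocol precondition was violated (e.g. S1 no-capture)."""
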