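"""Exception types."""


class SociometerError(Exception):
    """Base class for package errors."""


class ConfigError(SociometerError, ValueError):
    """A task design or run configuration is invalid."""


class ParameterError(SociometerError, ValueError):
    """A model parameter set violates its declared ranges."""


class FitError(SociometerError, RuntimeError):
    """Maximum-likelihood fitting failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
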