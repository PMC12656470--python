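"""Exception hierarchy."""


class GocaoError(Exception):
    """Base class for all package errors."""


class ParameterError(GocaoError, ValueError):
    """Invalid parameter value (non-positive scale, empty bank, ...)."""


class ConfigError(GocaoError, ValueError):
    """Invalid or unknown configuration key/value."""


class RegistrationError(GocaoError, RuntimeError):
    """Registration could not be completed; carries stage diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})
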