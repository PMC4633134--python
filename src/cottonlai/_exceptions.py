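"""Exception hierarchy shared across the package."""


class CottonLAIError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CottonLAIError, ValueError):
    """Invalid inputs: bad shapes, out-of-domain values, broken invariants."""


class FitError(CottonLAIError, RuntimeError):
    """An optimizer or least-squares fit failed or produced unusable output."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
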