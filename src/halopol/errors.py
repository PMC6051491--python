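"""Exception hierarchy shared across the toolkit."""


class HalopolError(Exception):
    """Base class for all package errors."""


class ValidationError(HalopolError, ValueError):
    """A parameter or input violates an invariant.

    ``field`` names the offending parameter so callers (and the CLI) can
    report it without parsing the message.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class FormatError(HalopolError, ValueError):
    """A tabular/sequence input file is malformed (missing column, bad role...)."""


class UnitError(HalopolError, ValueError):
    """An operation was applied to a trace in the wrong unit."""


class LocalizationError(HalopolError, RuntimeError):
    """Bead localization failed (no spot above the noise floor, or no convergence)."""


class FitConvergenceError(HalopolError, RuntimeError):
    """A nonlinear fit failed to converge after all restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class UndefinedRatioError(HalopolError, ZeroDivisionError):
    """The Tyr doublet ratio is undefined because the 830 cm^-1 area is ~0."""
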