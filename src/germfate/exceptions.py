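"""Exception types shared across the package."""


class GermfateError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(GermfateError, ValueError):
    """A simulation or pipeline configuration failed validation."""


class NoReferenceError(GermfateError, ValueError):
    """No feature is nonzero in every sample; the median-of-ratios
    pseudo-reference cannot be formed."""


class UndefinedTPMError(GermfateError, ValueError):
    """A sample column sums to zero, so TPM is undefined for it."""


class InsufficientDataError(GermfateError, ValueError):
    """Fewer observations than the operation's stated minimum."""


class ParseError(GermfateError, ValueError):
    """A text input failed to parse; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
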