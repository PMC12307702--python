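"""Exception hierarchy shared across the package."""


class Ki67EvalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Ki67EvalError):
    """A file does not conform to the expected format (e.g. missing columns)."""


class ValidationError(Ki67EvalError):
    """Input data violates a documented invariant (e.g. out-of-bounds point)."""


class FrameMismatchError(Ki67EvalError):
    """Two operands that must share a coordinate frame do not."""


class ExtentMismatchError(Ki67EvalError):
    """Two frames that should cover the same physical region do not."""


class ConfigurationError(Ki67EvalError):
    """A configuration value is invalid or infeasible."""


class DegenerateDataError(Ki67EvalError):
    """The input is degenerate for the requested computation (e.g. zero variance)."""
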