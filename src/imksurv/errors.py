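"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors exit 2 (click's default),
anything raised from the classes below exits 3.
"""


class IMKError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IMKError):
    """Inconsistent model configuration (mismatched lengths, bad modes, ...)."""


class DataValidationError(IMKError, ValueError):
    """Input data violate a documented invariant (negative dose, S > 1, ...)."""


class EstimationError(IMKError, RuntimeError):
    """An estimator cannot produce a meaningful result from the given data."""
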