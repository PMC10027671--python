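"""Exception hierarchy shared across the package."""


class PorekineticsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PorekineticsError):
    """A configuration is incomplete or internally inconsistent."""


class ValidationError(PorekineticsError, ValueError):
    """An input value violates a documented invariant."""


class EstimationError(PorekineticsError):
    """An estimator could not produce a result from the given data."""


class FittingError(PorekineticsError):
    """A maximum-likelihood fit failed to converge."""


class FormatError(PorekineticsError):
    """A file does not conform to the expected on-disk format."""


class UsageError(PorekineticsError):
    """An operation was called with incompatible arguments."""
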