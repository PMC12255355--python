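"""Exception hierarchy shared across the package."""


class PafluenceError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PafluenceError, ValueError):
    """Raised when a domain object is constructed with invalid fields."""


class ConfigurationError(PafluenceError, ValueError):
    """Raised when a run configuration is inconsistent or unusable."""


class EstimationError(PafluenceError, RuntimeError):
    """Raised when a fit has no valid windows or an empty aggregation range."""
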