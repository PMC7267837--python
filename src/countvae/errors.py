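"""Exception hierarchy shared across the package."""


class CountVaeError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(CountVaeError, ValueError):
    """Array dimensions are incompatible with the model or data."""


class DomainError(CountVaeError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class ConfigurationError(CountVaeError, ValueError):
    """An invalid option, tag or configuration combination was requested."""


class StateError(CountVaeError, RuntimeError):
    """Required mutable state (e.g. batch-norm running statistics) is missing."""


class UnsupportedModelError(CountVaeError, TypeError):
    """The operation does not apply to this model variant."""


class CalibrationError(CountVaeError, RuntimeError):
    """A calibration target could not be reached within the search bounds."""

    def __init__(self, message: str, achieved: float | None = None):
        super().__init__(message)
        self.achieved = achieved


class FormatError(CountVaeError, ValueError):
    """An input file violates its declared format."""
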