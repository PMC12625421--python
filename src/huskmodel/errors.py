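"""Exception hierarchy shared across the package."""


class HuskModelError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HuskModelError, ValueError):
    """An input lies outside the physical/mathematical domain of an operation."""


class InfeasibleError(DomainError):
    """No removal fraction can satisfy the requested regulatory limit."""


class EstimationError(HuskModelError, ValueError):
    """Parameter estimation failed (under-determined or non-identifiable data)."""


class CalibrationError(HuskModelError, ValueError):
    """A calibration curve is unusable for quantification."""


class ConfigurationError(HuskModelError, ValueError):
    """User-supplied configuration is inconsistent (e.g. overlapping windows)."""
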