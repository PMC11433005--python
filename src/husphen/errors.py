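"""Exception hierarchy shared by all pipeline stages.

Every error raised on invalid input derives from :class:`ValidationError`
(CLI exit code 2); statistical or numerical infeasibility derives from
:class:`InfeasibilityError` (CLI exit code 3).
"""


class HusphenError(Exception):
    """Base class for all package errors."""


class ValidationError(HusphenError, ValueError):
    """Invalid input, configuration or contract violation."""


class DomainError(ValidationError):
    """A numeric argument outside its mathematical domain."""


class ConfigurationError(ValidationError):
    """A required configuration value is missing or inconsistent."""


class AmbiguityError(ValidationError):
    """Duplicate records make a per-mouse computation ambiguous."""


class MissingDataError(ValidationError):
    """A required record (e.g. baseline timepoint) is absent."""


class WrongContextError(ValidationError):
    """An operation applied to data from the wrong measurement context."""


class UndefinedValueError(ValidationError):
    """The requested quantity is undefined for this input (e.g. 0/0)."""


class GeometryError(ValidationError):
    """ROI or mask geometry violates the image contract."""


class ResolutionError(GeometryError):
    """Too few pixels under an ROI for a stable estimate."""


class ROIAreaError(GeometryError):
    """ROI area outside the protocol tolerance."""


class DepthMismatchError(GeometryError):
    """Paired ROIs are not at comparable distance from the probe."""


class DegenerateMeasurementError(ValidationError):
    """A caliper measurement with coincident endpoints."""


class IncompleteSetError(ValidationError):
    """A multi-plane analysis is missing one of its required planes."""


class DesignError(ValidationError):
    """A statistical design violation (e.g. a subject in both diet arms)."""


class DependencyError(ValidationError):
    """A report stage is missing one of its upstream outputs."""


class InfeasibilityError(HusphenError):
    """A target or test cannot be satisfied by any parameter value."""


class InfeasibleTargetError(InfeasibilityError):
    """A waveform calibration target outside the attainable range."""


class InsufficientCyclesError(InfeasibilityError):
    """Fewer than three cardiac cycles detected in a Doppler trace."""


class ExtractionError(InfeasibilityError):
    """Doppler feature extraction produced inconsistent values."""
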