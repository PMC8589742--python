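"""Exception hierarchy shared across the package."""


class QmrnError(Exception):
    """Base class for all package-specific errors."""


class DesignError(QmrnError):
    """The study design is invalid (too few subjects/scans/readers, etc.)."""


class DegenerateRoiError(QmrnError):
    """A region of interest is empty or too small on an analysis slice."""


class GeometryError(QmrnError):
    """Acquisition geometries are incompatible (e.g. mismatched FOV)."""


class InsufficientDataError(QmrnError):
    """Too few data points survive for the requested operation."""


class InvalidSignalError(QmrnError):
    """Signal values violate a physical precondition (non-positive, etc.)."""


class FitError(QmrnError):
    """A model fit failed and the failure policy is 'fail'."""


class ConfigError(QmrnError):
    """A run configuration or provenance record is invalid."""
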