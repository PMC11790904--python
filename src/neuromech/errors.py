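"""Exception hierarchy shared across the package."""


class NeuromechError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NeuromechError):
    """Invalid configuration file or parameter set."""


class GeometryError(NeuromechError):
    """Phantom or mask geometry is inconsistent with the grid."""


class FitError(NeuromechError):
    """A curve/decay fit could not be performed."""


class NoContactError(FitError):
    """Approach curve never crosses the set-point current."""


class WindowTooSparseError(FitError):
    """Fewer than two samples inside the slope-fit window."""


class InvalidSlopeError(FitError):
    """Measured slope outside the physically admissible (0, s_inf] range."""


class InvalidModulusError(NeuromechError):
    """Young's modulus must be positive and finite (or flagged rigid)."""


class RegionError(NeuromechError):
    """Empty or out-of-bounds region of interest."""


class UndefinedCorrelationError(NeuromechError):
    """Correlation undefined (constant input)."""


class InsufficientSampleError(NeuromechError):
    """Too few observations for the requested statistical test."""


class InsufficientTrackError(NeuromechError):
    """Track too short for the requested metric."""
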