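"""Exception hierarchy shared across the package."""


class SynapkitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SynapkitError, ValueError):
    """A simulation or analysis parameter is out of its valid range."""


class WindowError(SynapkitError, ValueError):
    """A requested analysis window does not fit inside the trace."""


class UndefinedMetricError(SynapkitError, ValueError):
    """The metric is mathematically undefined on this input (e.g. zero amplitude)."""


class InputError(SynapkitError, ValueError):
    """Malformed or inconsistent input data."""


class GeometryError(SynapkitError, ValueError):
    """A geometric construction (extraction rectangle, ellipse fit) fails."""


class AmbiguousOrientationError(GeometryError):
    """The PSD mask is too close to circular for the major axis to be defined."""


class PlacementError(SynapkitError, RuntimeError):
    """Random object placement failed after bounded retries."""


class DegenerateDataError(SynapkitError, RuntimeError):
    """Resampling cannot produce a defined statistic on this dataset."""
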