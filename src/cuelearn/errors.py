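"""Exception hierarchy shared across the pipeline stages."""


class CuelearnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CuelearnError, ValueError):
    """Invalid generator / physics / run configuration."""


class SchemaError(CuelearnError, ValueError):
    """Tabular input does not match the documented schema."""


class SamplingError(CuelearnError, ValueError):
    """Time base is non-uniform or non-monotone beyond tolerance."""


class BoundaryError(CuelearnError, ValueError):
    """Peak window would exceed the recording; trial is flagged, not padded."""


class InsufficientDataError(CuelearnError, ValueError):
    """Operation requires more samples / frames / pairs than provided."""


class DegenerateGeometryError(CuelearnError, ValueError):
    """Landmark set is degenerate (coincident points)."""


class ResolutionError(CuelearnError, ValueError):
    """Integration step too coarse for reliable contact detection."""


class BallNotMovedError(CuelearnError, ValueError):
    """Target ball displacement below threshold; directional error undefined."""


class UndefinedMetricError(CuelearnError, ValueError):
    """Metric undefined for the given input (empty library, zero variance, ...)."""
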