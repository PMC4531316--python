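"""Exception hierarchy for the edge-tracking pipeline.

Each pipeline stage raises a distinct subclass so the orchestrator can
report which stage failed and with what diagnostic.
"""


class FretrackError(Exception):
    """Base class for all package errors."""


class ConfigError(FretrackError, ValueError):
    """Invalid configuration value (non-positive spacing, bad percentile, ...)."""


class FormatError(FretrackError, ValueError):
    """Input files malformed or inconsistent (shape/frame-count mismatch)."""


class GeometryError(FretrackError, ValueError):
    """Contour or band geometry violates a precondition (touches grid edge,
    empty band, too few windows)."""


class DetectionError(FretrackError, RuntimeError):
    """Boundary detection found no usable object."""


class TrackingError(FretrackError, RuntimeError):
    """Level-set evolution or correspondence failed to converge / too many
    conflicts."""


class ClassificationError(FretrackError, RuntimeError):
    """Region / cell classification not possible (no protrusion, no region)."""


class StatsError(FretrackError, ValueError):
    """Statistical operation on a degenerate sample."""


class ShapeError(FretrackError, ValueError):
    """Inconsistent array dimensions when assembling maps."""
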