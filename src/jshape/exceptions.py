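"""Exception hierarchy for the jshape pipeline."""


class JShapeError(Exception):
    """Base class for all jshape-specific errors."""


class MaskFormatError(JShapeError):
    """A volume or mask file could not be interpreted (e.g. missing spacing)."""


class EmptyRegionError(JShapeError):
    """An operation required a non-empty segmented region."""


class InsufficientPointsError(JShapeError):
    """Too few points to fit an ellipse (fewer than 3)."""


class DegenerateGeometryError(JShapeError):
    """The point cloud is (near-)collinear; no meaningful ellipse exists."""


class DegenerateAxisError(JShapeError):
    """Femur landmarks coincide; the anatomical axis is undefined."""


class ConfigError(JShapeError):
    """Inconsistent or incomplete study configuration."""


class EmptySummaryError(JShapeError):
    """No slice survived filtering; a per-muscle summary cannot be formed."""


class GenerationError(JShapeError):
    """Phantom generation failed (e.g. overlapping muscle labels)."""
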