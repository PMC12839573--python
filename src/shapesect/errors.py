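"""Exception hierarchy for shapesect."""


class ShapesectError(ValueError):
    """Base class for all shapesect errors."""


class InvalidContourError(ShapesectError):
    """Contour violates basic invariants (fewer than 3 vertices, repeated points)."""


class DegenerateAreaError(ShapesectError):
    """Enclosed area is numerically zero where a nonzero area is required."""


class InvalidMapError(ShapesectError):
    """Parameter map is not monotone non-decreasing with fixed endpoints."""


class ExteriorReferenceError(ShapesectError):
    """Reference point lies outside (or on) the contour where an interior point is required."""


class InvalidWindingError(ShapesectError):
    """Winding angle does not close up to +/-2*pi (non-simple contour or bad reference)."""


class AmbiguousEllipseError(ShapesectError):
    """Approximating ellipse has equal principal moments; rotation undefined."""


class UndefinedIndexError(ShapesectError):
    """Cluster-validity index undefined (all-singleton classes or coincident centroids)."""


class ParseError(ShapesectError):
    """Malformed contour file."""


class ExtractionError(ShapesectError):
    """Binary-mask boundary extraction failed."""
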