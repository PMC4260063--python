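"""Exception types shared across the package."""


class GeodensError(Exception):
    """Base class for all package-specific errors."""


class InvalidRegionError(GeodensError, ValueError):
    """Study-region polygon is empty, unclosed, self-intersecting or has zero area."""


class InvalidSpecError(GeodensError, ValueError):
    """Intensity specification violates its invariants (negative counts, spread <= 0, ...)."""


class InvalidParameterError(GeodensError, ValueError):
    """A numeric parameter lies outside its documented domain."""


class IncompatibleGridsError(GeodensError, ValueError):
    """Two raster surfaces do not share the same grid geometry."""


class EmptySurfaceError(GeodensError, ValueError):
    """A raster operation needs at least one non-NODATA cell."""


class EmptyInputError(GeodensError, ValueError):
    """An aggregation was asked for on an empty collection."""


class OutOfDomainError(GeodensError, ValueError):
    """A profile attribute lies outside the population's domain (e.g. age < 18)."""


class ParseError(GeodensError, ValueError):
    """A file does not conform to its declared format; message names the offending line."""
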