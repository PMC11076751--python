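"""Exception hierarchy for neuroplan.

All package errors derive from :class:`NeuroplanError` so callers can catch
one base class at CLI boundaries.
"""


class NeuroplanError(Exception):
    """Base class for all neuroplan errors."""


class InvalidSpecError(NeuroplanError, ValueError):
    """A phantom or cohort specification violates its invariants."""


class ResolutionError(NeuroplanError, ValueError):
    """Voxel pitch too coarse for the requested structure."""


class LabelNotFoundError(NeuroplanError, KeyError):
    """Requested label absent from a label volume."""


class GeometryError(NeuroplanError, ValueError):
    """Degenerate or invalid planar/mesh geometry."""


class InvalidInputError(NeuroplanError, ValueError):
    """Malformed input to a metric or geometry operation."""


class OffSurfaceError(NeuroplanError, ValueError):
    """Annotation point lies farther than tolerance from its layer mesh."""


class UndefinedMarginError(GeometryError):
    """Centroid ray through an edge midpoint misses the silhouette boundary."""


class ReproducibilityError(NeuroplanError, ValueError):
    """A stochastic operation was invoked without a seeded RNG."""


class SchemaError(NeuroplanError, ValueError):
    """An annotation or config file fails schema validation."""


class AlignmentError(NeuroplanError, ValueError):
    """Paired sample vectors are misaligned or contain missing pairs."""
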