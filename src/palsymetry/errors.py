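"""Exception hierarchy for palsymetry.

All package-specific failures derive from :class:`PalsymetryError` so callers
can catch one base class at pipeline boundaries.
"""


class PalsymetryError(Exception):
    """Base class for all palsymetry errors."""


class DimensionMismatchError(PalsymetryError):
    """Array shapes are inconsistent; message names the offending field."""


class ModelFormatError(PalsymetryError):
    """A morphable-model container file is missing, truncated or malformed."""


class PtsFormatError(PalsymetryError):
    """An iBUG .pts landmark file violates the dialect; message carries the line."""


class DegenerateGeometryError(PalsymetryError):
    """Geometry does not constrain the requested quantity (collinear points,
    coincident eye centroids, zero image-plane spread)."""


class RankDeficiencyError(PalsymetryError):
    """An unregularized least-squares system is singular."""


class SchemeMismatchError(PalsymetryError):
    """Two landmark sets bound to different schemes were combined."""


class RegionConfigError(PalsymetryError):
    """A region definition is empty, unknown or inconsistent across sessions."""


class UndefinedAsymmetryError(PalsymetryError):
    """Left/right asymmetry is undefined because both regions show zero motion."""
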