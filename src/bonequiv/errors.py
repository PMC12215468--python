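"""Exception hierarchy for the bonequiv pipeline."""


class BonequivError(Exception):
    """Base class for all pipeline errors."""


class EmptyMaskError(BonequivError):
    """A voxelization or mask produced no foreground voxels."""


class EmptySurfaceError(BonequivError):
    """Isosurface extraction on an all-background or all-foreground mask."""


class DegenerateGeometryError(BonequivError):
    """Point configuration too degenerate for rigid estimation (collinear, <3 points)."""


class EmptyFroiError(BonequivError):
    """FROI clipping retained no vertices."""


class DegenerateSampleError(BonequivError):
    """A statistical routine received a constant or too-small sample."""


class CorruptFixtureError(BonequivError):
    """The packaged reference table failed its checksum."""
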