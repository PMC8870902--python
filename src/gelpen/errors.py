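"""Exception hierarchy for the gelpen pipeline."""


class GelpenError(Exception):
    """Base class for all gelpen errors."""


class StackIOError(GelpenError):
    """Problem reading or writing an image stack or table."""


class GeometryError(GelpenError):
    """Missing or invalid voxel geometry."""


class ChannelError(GelpenError):
    """Channel-role assignment problem (missing channel, <2 channels, ...)."""


class SingularMatrixError(GelpenError):
    """Crosstalk mixing matrix is not invertible."""


class EmptyMaskError(GelpenError):
    """Validity mask has no true pixel; input is unusable downstream."""


class SurfaceError(GelpenError):
    """Surface extraction or fitting failed (flat columns, rank deficiency)."""


class DegenerateFitError(SurfaceError):
    """Too few valid pixels or rank-deficient design for the reference fit."""


class StalePeaksError(GelpenError):
    """A PeakSet does not match the penetration map it claims to come from."""
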