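"""Exception hierarchy.

All package-specific failures derive from :class:`CineAlignError` so callers
can catch one base class; each concrete error corresponds to a violated
precondition of a documented operation.
"""


class CineAlignError(Exception):
    """Base class for all cinealign errors."""


class InvalidPlaneError(CineAlignError, ValueError):
    """Imaging-plane axes are not orthonormal or spacing is not positive."""


class DegenerateAxisError(CineAlignError, ValueError):
    """Too few short-axis slices to fit a left-ventricular long axis."""


class InsufficientPointsError(CineAlignError, ValueError):
    """Point cloud too small for the requested neighborhood size."""


class RegistrationFailedError(CineAlignError, RuntimeError):
    """No correspondences inside the gating distance; registration aborted."""


class OpenContourError(CineAlignError, ValueError):
    """A short-axis LV contour required to be closed is open."""


class DegenerateCloudError(CineAlignError, ValueError):
    """Point cloud is (near-)coplanar; no tetrahedral mesh exists."""


class SeedError(CineAlignError, ValueError):
    """Interior seed point falls outside the tetrahedral mesh."""


class SeedConfigurationError(CineAlignError, ValueError):
    """Source and sink seeds overlap; the cut would be infinite."""


class OpenSurfaceError(CineAlignError, ValueError):
    """Surface expected to be a closed 2-manifold is open."""


class PlaneMismatchError(CineAlignError, ValueError):
    """Two planar regions that must share an imaging plane do not."""


class EmptyPhantomError(CineAlignError, ValueError):
    """Phantom geometry leaves one or more short-axis slices empty."""


class SchemaError(CineAlignError, ValueError):
    """Contour file does not match the documented JSON schema."""

    def __init__(self, field: str, message: str = ""):
        self.field = field
        super().__init__(f"invalid or missing field '{field}'" + (f": {message}" if message else ""))


class MissingAttributeError(CineAlignError, KeyError):
    """DICOM file lacks one of the three required geometry attributes."""

    def __init__(self, attribute: str):
        self.attribute = attribute
        super().__init__(f"DICOM file missing required attribute {attribute}")
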