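"""Exception hierarchy used across the package."""


class SeptamechError(Exception):
    """Base class for all package errors."""


class ParameterError(SeptamechError, ValueError):
    """Invalid user-supplied parameter."""


class GeometryError(SeptamechError):
    """Geometrically invalid input (non-simple curve, degenerate triangles, ...)."""


class SelfIntersectionError(GeometryError):
    """An offset operation would make the geometry self-intersect."""


class ConvergenceError(SeptamechError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AssemblyError(SeptamechError):
    """Model assembly failed (mismatched boundary, non-watertight result, ...)."""


class MeshQualityError(SeptamechError):
    """Mesh is invalid for analysis (inverted elements, singular system)."""


class ConstraintError(SeptamechError):
    """Rigid-body constraints could not be constructed or are inconsistent."""


class SamplingError(SeptamechError):
    """A probe or statistics request addresses an empty/invalid region."""
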