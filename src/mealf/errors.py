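"""Exception hierarchy for mealf."""


class MealfError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(MealfError, ValueError):
    """Cell or domain geometry violates a precondition."""


class ConfigurationError(MealfError, ValueError):
    """Invalid layout or run configuration."""


class MeshingError(MealfError, RuntimeError):
    """Mesh generation failed (degenerate or colliding geometry)."""


class AssemblyError(MealfError, RuntimeError):
    """FEM system assembly failed (missing labels, bad interfaces)."""


class SolverError(MealfError, RuntimeError):
    """Linear solve failed or did not reach the requested residual."""


class ResolutionError(MealfError, ValueError):
    """A region contains no mesh element centroids at the current resolution."""
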