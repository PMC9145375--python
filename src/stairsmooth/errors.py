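"""Exception hierarchy.

Errors are split into the categories the command line maps to distinct
exit codes: structural (topology), geometric, numerical, and input/usage.
"""


class StairsmoothError(Exception):
    """Base class for all package errors."""


class MeshStructureError(StairsmoothError):
    """Topological defect: non-manifold edge, open boundary, degenerate face."""


class GeometryError(StairsmoothError):
    """Geometric degeneracy: zero-length edge, zero area, failed bracket."""


class NumericalError(StairsmoothError):
    """Linear-solve or integration failure."""


class InputError(StairsmoothError):
    """Invalid user-supplied data or configuration."""
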