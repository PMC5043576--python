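"""Exception hierarchy.

All package-specific failures derive from :class:`IgtandemError` so callers
can catch one base class at pipeline level while tests assert on the
specific subclass.
"""


class IgtandemError(Exception):
    """Base class for all igtandem errors."""


class ParseError(IgtandemError):
    """A structure, trajectory or table file could not be parsed."""


class SelectionError(IgtandemError):
    """A malformed atom-selection query."""


class DihedralUndefinedError(IgtandemError):
    """Dihedral requested for (near-)collinear or coincident points."""


class DegenerateGeometryError(IgtandemError):
    """Geometry is too degenerate for the requested operation
    (e.g. spherical inertia tensor, <3 superposition atoms)."""


class NoTransitionError(IgtandemError):
    """A melting curve shows no detectable unfolding transition."""


class FitConvergenceError(IgtandemError):
    """Nonlinear fit failed to converge; message carries diagnostics."""


class StageError(IgtandemError):
    """A pipeline stage failed; message names the stage."""
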