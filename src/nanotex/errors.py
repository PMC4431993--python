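"""Exception hierarchy shared by all modules."""


class NanotexError(Exception):
    """Base class for all package errors."""


class ParseError(NanotexError):
    """A text file could not be parsed into numbers."""


class ShapeError(NanotexError):
    """Rows of a matrix file are ragged or the grid shape is inconsistent."""


class GridError(NanotexError):
    """XYZ triplets do not form a complete regular lattice."""


class ValidationError(NanotexError):
    """A height map violates an invariant (non-finite values, bad sizes)."""


class CalibrationError(NanotexError):
    """Pixel sizes of two objects that must match do not."""


class ParameterError(NanotexError):
    """A parameter is outside its admissible range."""


class GeometryError(NanotexError):
    """A geometric construction is impossible (tip grid too small, ...)."""


class FixtureError(NanotexError):
    """A requested exact fixture is geometrically inconsistent."""


class FitError(NanotexError):
    """A log-log linear fit has too few or degenerate points."""


class DegenerateSurfaceError(NanotexError):
    """An estimator is undefined on a zero-variance surface."""
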