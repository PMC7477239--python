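"""Exception hierarchy.

All package errors derive from :class:`OnhError`; most double as the builtin
exception a caller would naturally catch (``ValueError``, ``LookupError``).
"""


class OnhError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(OnhError, ValueError):
    """Invalid simulation or analysis parameters."""


class GeometryError(OnhError, ValueError):
    """Invalid or unusable geometry (self-intersecting ring, out-of-field ellipse...)."""


class DegenerateGeometryError(GeometryError):
    """Too few or collinear points for a plane fit."""


class EmptyLCError(OnhError, ValueError):
    """No delineated lamina cribrosa node projects inside the BMO polygon."""


class RimConstraintError(OnhError, ValueError):
    """No admissible ILM triangle satisfies the neuroretinal-rim constraint."""


class FormatError(OnhError, ValueError):
    """Malformed interchange file; the message names the offending field or cell."""


class FixtureLookupError(OnhError, LookupError):
    """Unknown packaged fixture name."""


class SelectionError(OnhError, ValueError):
    """A row/column selection matched nothing."""


class InsufficientDataError(OnhError, ValueError):
    """Fewer observations than the statistic requires."""


class DegenerateVarianceError(OnhError, ValueError):
    """Zero residual variance where a correlation is requested."""
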