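"""Exception hierarchy for pulptherm.

All package errors derive from :class:`PulpthermError` so callers can catch
everything with one clause; specific subclasses signal which contract was
violated.
"""


class PulpthermError(Exception):
    """Base class for all pulptherm errors."""


class InvalidParameterError(PulpthermError, ValueError):
    """A parameter violates its documented invariant (non-positive size,
    degenerate extent, nesting violation, ...)."""


class InvalidLabelError(PulpthermError, KeyError):
    """A tissue label code or name is not one of the known values."""


class MaterialLookupError(PulpthermError, KeyError):
    """Requested material is not registered in the library."""


class PulpExposureError(PulpthermError):
    """A cavity design would carve into, or too close to, the pulp chamber."""


class EmptyCavityError(PulpthermError):
    """A cavity design removes no tooth material."""


class ConfigurationError(PulpthermError):
    """Inconsistent simulation setup (no source surface, missing material,
    intact phantom used where a restored one is required, ...)."""


class MissingTissueError(PulpthermError):
    """A requested tissue is absent from the grid or history."""


class SolverError(PulpthermError):
    """The linear solver failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class NumericalFailureError(PulpthermError):
    """Non-finite temperatures appeared during time integration."""


class DegenerateWindowError(PulpthermError, ValueError):
    """Line-fit window has zero width (t1 == t2)."""


class InsufficientDataError(PulpthermError):
    """A sensor series is too short for the requested analysis."""


class IncompleteInputError(PulpthermError):
    """A comparative summary is missing one or more cavity designs."""
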