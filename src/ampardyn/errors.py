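"""Exception hierarchy shared across the package."""


class AmpardynError(Exception):
    """Base class for all package errors."""


class FormatError(AmpardynError):
    """File could not be parsed in the declared or detected format."""


class NotFoundError(AmpardynError):
    """A requested model, residue or atom is absent."""


class EmptySelectionError(AmpardynError):
    """An atom selection matched nothing."""


class DegenerateGeometryError(AmpardynError):
    """Geometry is ill-conditioned (collinear points, zero-length vectors)."""


class ParameterError(AmpardynError):
    """A parameter violates its stated domain."""


class FitError(AmpardynError):
    """A least-squares fit failed to converge or the data are degenerate."""


class InsufficientDataError(AmpardynError):
    """Fewer data than the method requires."""


class ComparabilityError(AmpardynError):
    """Two objects cannot be compared (e.g. footprints at different cutoffs)."""


class StabilityError(AmpardynError):
    """A simulated trajectory left the guarded domain."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
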