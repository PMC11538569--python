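"""Exception types shared across the package."""


class SonolensError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SonolensError, ValueError):
    """A numeric or structural argument violates a precondition."""


class SingularEvaluationError(SonolensError):
    """An evaluation point fell inside the singularity guard of a point source."""


class GeometryError(SonolensError):
    """Grids, planes, slabs or lines are mutually inconsistent."""


class InvalidStateError(SonolensError):
    """An operation was applied to an object in the wrong state."""


class InsufficientPeaksError(SonolensError):
    """Fewer local maxima were found than requested."""

    def __init__(self, requested: int, found: int):
        self.requested = requested
        self.found = found
        super().__init__(f"requested {requested} peaks but found only {found}")
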