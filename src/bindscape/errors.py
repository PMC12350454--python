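"""Exception hierarchy shared by all analysis stages."""


class BindscapeError(Exception):
    """Base class for all package errors."""


class ParseError(BindscapeError):
    """A file could not be parsed; the message names the offending line."""


class EmptyInputError(BindscapeError):
    """An input contained no usable records (zero atoms, empty selection...)."""


class DimensionError(BindscapeError):
    """Shapes or atom counts of two objects do not agree."""


class ValidationError(BindscapeError):
    """A record violates an invariant (missing GB field, bad radius...)."""


class SelectionSyntaxError(BindscapeError):
    """The atom-selection query could not be parsed."""


class DegenerateGeometryError(BindscapeError):
    """Too few or collinear points for a rigid superposition."""


class ParameterError(BindscapeError):
    """A numerical parameter is outside its valid domain."""


class StabilityError(BindscapeError):
    """An integrator step size is too large for the potential."""


class ClashError(BindscapeError):
    """Two atoms are unphysically close for a pairwise energy term."""


class StageError(BindscapeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
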