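"""Exception hierarchy shared across the package."""


class HarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HarError):
    """A file does not match the declared sensor layout (e.g. missing column)."""


class IntegrityError(HarError):
    """Channel/label tracks are inconsistent (ragged lengths, missing samples)."""


class ParameterError(HarError, ValueError):
    """An argument is outside its valid range."""


class GeometryError(HarError, ValueError):
    """Kernel/pool geometry is incompatible with the input shape."""


class ConfigurationError(HarError):
    """A network specification cannot be realised (infeasible layer stack)."""


class TrainingDivergenceError(HarError):
    """The training loss became non-finite; carries the offending epoch."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class AnalysisError(HarError):
    """An analysis has no defined result (e.g. correlations of constant data)."""
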