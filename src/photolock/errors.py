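"""Exception hierarchy shared across the pipeline."""


class PhotolockError(Exception):
    """Base class for all package errors."""


class ParameterError(PhotolockError, ValueError):
    """A processing parameter is outside its valid range."""


class ConfigurationError(PhotolockError, ValueError):
    """A simulation or run configuration is invalid."""


class ScheduleError(PhotolockError, ValueError):
    """A trial schedule is inconsistent (overlap, out of bounds)."""


class ShapeError(PhotolockError, ValueError):
    """Array lengths or shapes do not match."""


class NumericDomainError(PhotolockError, ValueError):
    """A value left the numeric domain an operation requires."""


class DegenerateFitError(PhotolockError, ValueError):
    """A regression or normalization has no unique solution."""


class DataError(PhotolockError, ValueError):
    """Input data violate a structural precondition."""


class StageError(PhotolockError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
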