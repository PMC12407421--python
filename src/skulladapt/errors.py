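"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`SkullAdaptError`, so callers can catch one type at a pipeline
boundary.  Argument-validation failures additionally derive from
:class:`ValueError` to behave well in generic code.
"""


class SkullAdaptError(Exception):
    """Base class for all errors raised by skulladapt."""


class ArgumentError(SkullAdaptError, ValueError):
    """An operation was called with invalid arguments."""


class DegenerateMeshError(SkullAdaptError, ValueError):
    """A mesh violates the non-degeneracy requirements of an operation."""


class ObjParseError(SkullAdaptError, ValueError):
    """A Wavefront OBJ file could not be parsed.

    Attributes
    ----------
    line_number : int
        1-based line number of the offending record.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DegenerateViewError(SkullAdaptError, ValueError):
    """The mesh is entirely behind the camera for the requested pose."""


class SplitInfeasibleError(SkullAdaptError, ValueError):
    """A specimen-level split cannot satisfy its constraints."""


class RegimeDataError(SkullAdaptError, ValueError):
    """A training regime is missing a data stream it requires."""


class TrainingDivergedError(SkullAdaptError, RuntimeError):
    """Training produced a non-finite loss."""


class CapabilityError(SkullAdaptError, RuntimeError):
    """A requested capability is unavailable (e.g. missing model tap or weights)."""


class UndefinedSilhouetteError(SkullAdaptError, ValueError):
    """A silhouette score is undefined (fewer than two labels in a subset)."""


class StageError(SkullAdaptError, RuntimeError):
    """An experiment stage failed; names the stage and config source."""

    def __init__(self, stage: str, config_path, cause: BaseException):
        super().__init__(f"stage '{stage}' failed (config: {config_path}): {cause}")
        self.stage = stage
        self.config_path = config_path
        self.__cause__ = cause
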