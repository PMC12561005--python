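"""Exception hierarchy.

Every error raised by this package derives from :class:`CafproxError`, so
callers (and the CLI) can catch one base class. Subclasses map onto the
failure modes of the individual pipeline stages.
"""


class CafproxError(Exception):
    """Base class for all cafprox errors."""


class ConfigError(CafproxError, ValueError):
    """Invalid configuration or parameter value."""


class SchemaError(CafproxError):
    """Input file violates the documented schema (e.g. missing column/role)."""


class RowParseError(CafproxError):
    """A data row failed to parse; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class IntegrityError(CafproxError):
    """Semantically invalid data (duplicate ids, unknown cell type, ...)."""


class GeometryError(CafproxError):
    """Invalid region geometry (self-intersection, broken invariants)."""


class PlacementError(CafproxError):
    """ROI placement could not satisfy the requested configuration."""

    def __init__(self, message: str, achieved_surface: int = 0, achieved_deep: int = 0):
        self.achieved_surface = achieved_surface
        self.achieved_deep = achieved_deep
        super().__init__(
            f"{message} (achieved {achieved_surface} surface, {achieved_deep} deep)"
        )


class EmptyTargetError(CafproxError):
    """Nearest-neighbor query against an empty target set."""


class UndefinedRatioError(CafproxError):
    """CAF-per-reference ratio requested with zero pooled reference cells."""


class NoSolutionError(CafproxError, ValueError):
    """Dispersion calibration target outside the attainable range."""


class SimulationError(CafproxError):
    """Point simulation failed (e.g. rejection sampling exhausted)."""


class StageError(CafproxError):
    """Pipeline stage failure; tags the failing stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
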