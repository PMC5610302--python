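"""Exception types shared across the package."""


class GeometryError(ValueError):
    """Raised when a geometric precondition is violated (lesion outside the
    grid, warp radius smaller than half the coil width, ...)."""


class SingularityError(ValueError):
    """Raised when a field point lies within the guard distance of the
    conductor, where the filament model diverges."""

    def __init__(self, message: str, guard_m: float, point_index: int | None = None):
        super().__init__(message)
        self.guard_m = guard_m
        self.point_index = point_index


class ConfigError(ValueError):
    """Raised for invalid or contradictory pipeline configuration."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
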