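"""Exception hierarchy shared across the package."""


class GlandSegError(Exception):
    """Base class for all glandseg errors."""


class InvalidParameterError(GlandSegError, ValueError):
    """A parameter is outside its documented range."""


class ShapeError(GlandSegError, ValueError):
    """Two rasters that must share a shape do not."""


class FormatError(GlandSegError, ValueError):
    """A file on disk is not in an accepted raster format."""


class InsufficientTissueError(GlandSegError, ValueError):
    """Too few tissue (non-background) pixels to estimate a stain basis."""


class InvalidBasisError(GlandSegError, ValueError):
    """A stain basis is degenerate (rank-deficient) or malformed."""


class PlacementError(GlandSegError, RuntimeError):
    """The synthetic-tissue generator could not place all requested glands."""


class DataError(GlandSegError, ValueError):
    """A manifest or dataset is empty, inconsistent, or missing files."""


class DivergenceError(GlandSegError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class DegenerateStatsError(GlandSegError, ValueError):
    """Normalization statistics are degenerate (zero-variance channel)."""


class PairingError(GlandSegError, ValueError):
    """Prediction and ground-truth directories do not pair up one-to-one."""

    def __init__(self, message: str, orphans: list[str] | None = None):
        super().__init__(message)
        self.orphans = orphans or []


class UndefinedMetricError(GlandSegError, ValueError):
    """A metric is undefined for the given inputs (e.g. empty mask)."""
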