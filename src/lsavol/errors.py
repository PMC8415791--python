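"""Exception hierarchy for the lsavol pipeline.

Every stage raises a subclass of :class:`LsavolError` so callers can
distinguish pipeline failures from programming errors.
"""


class LsavolError(Exception):
    """Base class for all lsavol errors."""


class ValidationError(LsavolError):
    """Input data violates a documented invariant (non-finite voxels, bad spacing...)."""


class DimensionalityError(ValidationError):
    """An image does not have the expected number of spatial dimensions."""


class GeometryError(LsavolError):
    """Grids, spacings or slabs are inconsistent with each other."""


class SizingError(GeometryError):
    """A grid is too small for the requested operation."""


class LegendError(LsavolError, KeyError):
    """A region name is not present in a label-mask legend."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class SelectionError(LsavolError):
    """The threshold-selection walk never met its stopping rule."""


class DegenerateInputError(LsavolError):
    """Input has no variance / is constant where variation is required."""


class SeedError(LsavolError):
    """A seed voxel could not be associated with any suprathreshold vessel."""


class RootingError(LsavolError):
    """A skeleton graph could not be attached to a parent artery or seed."""


class CohortError(LsavolError):
    """A cohort has too few valid cases for statistics."""


class PipelineStageError(LsavolError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
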