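"""Exception hierarchy shared across the package."""


class VoxeloptError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VoxeloptError, ValueError):
    """A parameter value is outside its valid domain (non-positive scale,
    out-of-bounds search point, sub-voxel signal scale, ...)."""


class InputError(VoxeloptError, ValueError):
    """Input data violate a structural precondition (mixed grids, empty
    cohort, group too small for the requested sub-sampling plan, ...)."""


class FormatError(VoxeloptError, ValueError):
    """A file could not be parsed as the expected on-disk format."""


class EvaluationError(VoxeloptError, RuntimeError):
    """An objective evaluation failed in a way that should be surfaced to
    the optimizer as a worst-case observation rather than a crash."""
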