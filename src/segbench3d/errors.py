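"""Exception hierarchy shared across the package.

Every error the library raises deliberately derives from
:class:`SegbenchError`, so CLI wrappers can map any validation failure to a
single non-zero exit code while programming errors still surface as ordinary
Python exceptions.
"""


class SegbenchError(Exception):
    """Base class for all deliberate segbench3d errors."""


class FormatError(SegbenchError):
    """An input file is not in a supported on-disk format."""


class ValidationError(SegbenchError):
    """Input values violate a documented precondition or invariant."""


class ShapeMismatchError(ValidationError):
    """Two stacks that must share a shape do not."""

    def __init__(self, shape_a, shape_b, what="stacks"):
        super().__init__(f"{what} have mismatching shapes: {tuple(shape_a)} vs {tuple(shape_b)}")
        self.shape_a = tuple(shape_a)
        self.shape_b = tuple(shape_b)


class SeedRejectedError(ValidationError):
    """A region-growing seed lies outside the requested intensity range."""

    def __init__(self, seed, intensity, theta_min, theta_max):
        super().__init__(
            f"seed {seed.object_id} at (x={seed.x}, y={seed.y}, z={seed.z}) has intensity "
            f"{intensity}, outside [{theta_min}, {theta_max}]"
        )
        self.seed = seed
        self.intensity = intensity


class WandMissError(ValidationError):
    """The rightward wand scan found no in-range pixel."""

    def __init__(self, slice_number, start_x, start_y):
        super().__init__(
            f"no in-range pixel right of (x={start_x}, y={start_y}) on slice {slice_number}"
        )


class DegenerateHistogramError(ValidationError):
    """A histogram with fewer than two populated bins admits no threshold."""


class OverlapError(ValidationError):
    """Two objects with different ids claim the same voxel."""
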