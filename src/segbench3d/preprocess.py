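"""Slice-wise median smoothing applied ahead of any segmentation step."""

from __future__ import annotations

from dataclasses import dataclass

from scipy import ndimage

from .errors import ValidationError
from .stack_io import IntensityStack


@dataclass(frozen=True)
class FilterSpec:
    """Square median window of side ``2 * radius + 1``; radius 0 = identity."""

    radius: int = 3

    def __post_init__(self):
        if self.radius < 0:
            raise ValidationError(f"filter radius must be >= 0, got {self.radius}")

    @property
    def window(self) -> int:
        return 2 * self.radius + 1


def median_filter_2d(stack: IntensityStack, spec: FilterSpec = FilterSpec(3)) -> IntensityStack:
    """Median-filter each slice independently with a square window.

    Borders are edge-replicated. With an odd window and integer input the
    median is always a member of the window, so the value set never grows.
    """
    if spec.radius == 0:
        return IntensityStack(
            voxels=stack.voxels.copy(),
            bit_depth=stack.bit_depth,
            calibration=stack.calibration,
        )
    filtered = ndimage.median_filter(
        stack.voxels, size=(1, spec.window, spec.window), mode="nearest"
    )
    return IntensityStack(voxels=filtered, bit_depth=stack.bit_depth, calibration=stack.calibration)
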