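"""Binary-mask and labelled-stack construction.

Three routes produce ground truth from a calibrated grayscale stack:

1. slice-based wand ROIs driven by (startX, startY, theta_min, theta_max)
   records, evaluated on the median-filtered stack;
2. seeded 3D connected-threshold region growing;
3. dual-threshold growing that picks a shallow or deep theta_min per seed
   according to a demarcation slice, compensating depth-dependent signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import OverlapError, SeedRejectedError, ValidationError, WandMissError
from .labelling import structure_2d, structure_3d
from .preprocess import FilterSpec, median_filter_2d
from .stack_io import BinaryMask, IntensityStack, LabelStack, RoiParams, SeedRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowParams:
    """Seeded connected-threshold growth parameters."""

    seed: SeedRecord
    theta_min: int
    theta_max: Optional[int] = None
    connectivity: int = 26

    def __post_init__(self):
        if self.theta_max is not None and self.theta_min > self.theta_max:
            raise ValidationError(f"thetaMin {self.theta_min} > thetaMax {self.theta_max}")


@dataclass(frozen=True)
class DualThresholdConfig:
    """Depth-compensating segmentation: one threshold per depth class.

    ``demarcation_slice`` is 1-based; seeds on a slice <= demarcation use
    ``theta_shallow``, deeper seeds use ``theta_deep``.
    """

    seeds: Sequence[SeedRecord]
    theta_shallow: int
    theta_deep: int
    demarcation_slice: int


@dataclass
class DualThresholdResult:
    labels: LabelStack
    skipped_seeds: list = field(default_factory=list)  # (SeedRecord, intensity, theta_min)
    collisions: list = field(default_factory=list)  # (SeedRecord, winning object id)


def _check_in_bounds(stack_shape, x, y, z, what="point"):
    Z, H, W = stack_shape
    if not (0 <= z < Z and 0 <= y < H and 0 <= x < W):
        raise ValidationError(
            f"{what} (x={x}, y={y}, z={z}) outside stack bounds (Z={Z}, H={H}, W={W})"
        )


def apply_global_threshold(
    stack: IntensityStack, theta_min: int, theta_max: Optional[int] = None
) -> BinaryMask:
    """Closed-interval threshold: foreground iff theta_min <= v <= theta_max."""
    if theta_max is None:
        theta_max = stack.max_value
    if theta_min > theta_max:
        raise ValidationError(f"thetaMin {theta_min} > thetaMax {theta_max}")
    mask = (stack.voxels >= theta_min) & (stack.voxels <= theta_max)
    return BinaryMask(mask=mask.astype(np.uint8), calibration=stack.calibration)


def region_grow_3d(stack: IntensityStack, params: GrowParams) -> BinaryMask:
    """Grow the maximal connected in-range region containing the seed.

    The result is exactly the connected component of
    ``{v : theta_min <= I(v) <= theta_max}`` that contains the seed, under
    the requested connectivity; it does not depend on any visit order.
    """
    seed = params.seed
    _check_in_bounds(stack.shape, seed.x, seed.y, seed.z, what=f"seed {seed.object_id}")
    theta_max = params.theta_max if params.theta_max is not None else stack.max_value
    intensity = int(stack.voxels[seed.z, seed.y, seed.x])
    if not (params.theta_min <= intensity <= theta_max):
        raise SeedRejectedError(seed, intensity, params.theta_min, theta_max)
    in_range = (stack.voxels >= params.theta_min) & (stack.voxels <= theta_max)
    labelled, _ = ndimage.label(in_range, structure=structure_3d(params.connectivity))
    component = labelled == labelled[seed.z, seed.y, seed.x]
    return BinaryMask(mask=component.astype(np.uint8), calibration=stack.calibration)


def wand_roi(
    slice_image: np.ndarray,
    start_x: int,
    start_y: int,
    theta_min: int,
    theta_max: int,
    slice_number: int = 1,
) -> np.ndarray:
    """Wand-style 2D ROI: rightward scan, contour trace, filled interior.

    Scans in +x from the start point for the first pixel whose intensity
    falls in ``[theta_min, theta_max]``, takes the 8-connected in-range
    component containing it, and returns it with interior holes filled —
    the filled interior of the clockwise outer contour.
    """
    slice_image = np.asarray(slice_image)
    if slice_image.ndim != 2:
        raise ValidationError(f"wand operates on a 2D slice, got shape {slice_image.shape}")
    H, W = slice_image.shape
    if not (0 <= start_y < H and 0 <= start_x < W):
        raise ValidationError(f"start point (x={start_x}, y={start_y}) outside slice {H}x{W}")
    row = slice_image[start_y, start_x:]
    in_range_row = (row >= theta_min) & (row <= theta_max)
    hits = np.flatnonzero(in_range_row)
    if hits.size == 0:
        raise WandMissError(slice_number, start_x, start_y)
    hit_x = start_x + int(hits[0])
    in_range = (slice_image >= theta_min) & (slice_image <= theta_max)
    labelled, _ = ndimage.label(in_range, structure=structure_2d(8))
    component = labelled == labelled[start_y, hit_x]
    return ndimage.binary_fill_holes(component)


def build_gt_from_roi_params(
    stack: IntensityStack,
    params: Sequence[RoiParams],
    filter_spec: FilterSpec = FilterSpec(3),
    on_overlap: str = "error",
) -> tuple:
    """Build (BinaryMask, LabelStack) ground truth from wand ROI records.

    The stack is median-filtered once; each record's ROI is computed on its
    filtered slice; all ROIs sharing an objectId form one 3D object. Voxels
    claimed by two different ids raise :class:`OverlapError` unless
    ``on_overlap="last-wins"``.
    """
    if on_overlap not in ("error", "last-wins"):
        raise ValidationError(f"on_overlap must be 'error' or 'last-wins', got {on_overlap!r}")
    Z, H, W = stack.shape
    filtered = median_filter_2d(stack, filter_spec)
    labels = np.zeros(stack.shape, dtype=np.int64)
    for p in params:
        if not (0 <= p.slice_index < Z):
            raise ValidationError(
                f"ROI for object {p.object_id} names slice {p.slice_index + 1}, "
                f"stack has {Z} slices"
            )
        roi = wand_roi(
            filtered.voxels[p.slice_index],
            p.start_x,
            p.start_y,
            p.theta_min,
            p.resolve_theta_max(stack.bit_depth),
            slice_number=p.slice_index + 1,
        )
        existing = labels[p.slice_index]
        clash = roi & (existing != 0) & (existing != p.object_id)
        if clash.any():
            if on_overlap == "error":
                ys, xs = np.nonzero(clash)
                other = int(existing[ys[0], xs[0]])
                raise OverlapError(
                    f"objects {other} and {p.object_id} both claim voxel "
                    f"(x={int(xs[0])}, y={int(ys[0])}, slice={p.slice_index + 1})"
                )
            logger.warning(
                "object %d overwrites %d voxels of other objects on slice %d",
                p.object_id,
                int(clash.sum()),
                p.slice_index + 1,
            )
        existing[roi] = p.object_id
    mask = BinaryMask(mask=(labels > 0).astype(np.uint8), calibration=stack.calibration)
    return mask, LabelStack(labels=labels, calibration=stack.calibration)


def grow_seeds(
    stack: IntensityStack,
    seeds: Sequence[SeedRecord],
    theta_min: int,
    theta_max: Optional[int] = None,
    connectivity: int = 26,
) -> LabelStack:
    """Grow every seed at one threshold into a labelled stack.

    Unlike :func:`dual_threshold_segment`, an out-of-range seed is a hard
    error here. Collisions resolve first-seed-wins.
    """
    labels = np.zeros(stack.shape, dtype=np.int64)
    for seed in seeds:
        grown = region_grow_3d(
            stack,
            GrowParams(seed=seed, theta_min=theta_min, theta_max=theta_max, connectivity=connectivity),
        )
        region = grown.mask.astype(bool) & (labels == 0)
        labels[region] = seed.object_id
    return LabelStack(labels=labels, calibration=stack.calibration)


def multi_seed_grow(
    stack: IntensityStack,
    seeds: Sequence[SeedRecord],
    theta_min: int,
    theta_max: Optional[int] = None,
    connectivity: int = 26,
) -> DualThresholdResult:
    """Grow every seed at one threshold; labels carry the seed object ids."""
    cfg = DualThresholdConfig(
        seeds=seeds,
        theta_shallow=theta_min,
        theta_deep=theta_min,
        demarcation_slice=stack.shape[0],
    )
    return dual_threshold_segment(stack, cfg, connectivity=connectivity, theta_max=theta_max)


def dual_threshold_segment(
    stack: IntensityStack,
    cfg: DualThresholdConfig,
    connectivity: int = 26,
    theta_max: Optional[int] = None,
) -> DualThresholdResult:
    """Depth-compensated multi-seed segmentation.

    Seeds whose 1-based slice is <= the demarcation slice grow with
    ``theta_shallow``, the rest with ``theta_deep``; theta_max defaults to
    the bit-depth maximum. A seed below its threshold is skipped with a
    warning (listed in the result), never a hard failure. When two seeds
    grow into the same voxels the first seed wins and the collision is
    recorded.
    """
    if theta_max is None:
        theta_max = stack.max_value
    labels = np.zeros(stack.shape, dtype=np.int64)
    result = DualThresholdResult(
        labels=LabelStack(labels=labels, calibration=stack.calibration)
    )
    for seed in cfg.seeds:
        _check_in_bounds(stack.shape, seed.x, seed.y, seed.z, what=f"seed {seed.object_id}")
        theta_min = (
            cfg.theta_shallow if (seed.z + 1) <= cfg.demarcation_slice else cfg.theta_deep
        )
        try:
            grown = region_grow_3d(
                stack,
                GrowParams(
                    seed=seed,
                    theta_min=theta_min,
                    theta_max=theta_max,
                    connectivity=connectivity,
                ),
            )
        except SeedRejectedError as exc:
            logger.warning("skipping seed: %s", exc)
            result.skipped_seeds.append((seed, exc.intensity, theta_min))
            continue
        region = grown.mask.astype(bool)
        taken = region & (labels != 0)
        if taken.any():
            winner = int(labels[taken][0])
            logger.warning(
                "seed %d grew into %d voxels already owned by object %d; first seed wins",
                seed.object_id,
                int(taken.sum()),
                winner,
            )
            result.collisions.append((seed, winner))
            region &= labels == 0
        labels[region] = seed.object_id
    return result
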