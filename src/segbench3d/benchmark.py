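"""Segmentation performance evaluation against a labelled ground truth.

Pixel level: true/false positive/negative voxel tallies and the derived
precision ``p = tp / (tp + fp)``, recall ``r = tp / (tp + fn)`` and
F-measure ``F = 2pr / (p + r)``, per stack and per slice.

Object level: a bipartite overlap graph between GT and MS labels classifies
every label as one-to-one, split (one GT matched by several MS), merged
(one MS matched by several GT), false-positive MS or false-negative GT —
again per stack and per slice, where a slice "object" is the cross-section
of a 3D label (so a report can name the exact slice where a merge occurs).

Degenerate conventions (both segmentations empty -> p = r = F = 1; tp = 0
with a non-empty union -> p = r = F = 0) keep every metric total while
preserving the identity that a ground truth benchmarked against itself
scores 1 everywhere.
"""

from __future__ import annotations

import csv
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError, ValidationError
from .stack_io import BinaryMask, IntensityStack, LabelStack


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class PixelMetrics:
    precision: float
    recall: float
    fmeasure: float


@dataclass
class CorrespondenceReport:
    """Object-level match classification between GT and MS labels."""

    n_gt_objects: int
    n_ms_objects: int
    one_to_one: list = field(default_factory=list)  # (gt_label, ms_label)
    split: list = field(default_factory=list)  # (gt_label, [ms_labels])
    merged: list = field(default_factory=list)  # (ms_label, [gt_labels])
    fp_objects: list = field(default_factory=list)  # [ms_labels]
    fn_objects: list = field(default_factory=list)  # [gt_labels]


@dataclass
class SliceBenchmark:
    slice_index: int  # 0-based
    confusion: ConfusionCounts
    metrics: PixelMetrics
    correspondence: CorrespondenceReport


@dataclass
class BenchmarkReport:
    stack_confusion: ConfusionCounts
    stack_metrics: PixelMetrics
    stack_correspondence: CorrespondenceReport
    slices: list = field(default_factory=list)  # [SliceBenchmark]


def _require_same_shape(gt: LabelStack, ms: LabelStack):
    if tuple(gt.shape) != tuple(ms.shape):
        raise ShapeMismatchError(gt.shape, ms.shape, what="GT and MS stacks")


def _confusion(gt_fg: np.ndarray, ms_fg: np.ndarray) -> ConfusionCounts:
    tp = int(np.count_nonzero(gt_fg & ms_fg))
    fp = int(np.count_nonzero(~gt_fg & ms_fg))
    fn = int(np.count_nonzero(gt_fg & ~ms_fg))
    tn = gt_fg.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_counts(gt: LabelStack, ms: LabelStack) -> ConfusionCounts:
    """Whole-stack voxel confusion; foreground = label > 0."""
    _require_same_shape(gt, ms)
    return _confusion(gt.labels > 0, ms.labels > 0)


def confusion_counts_per_slice(gt: LabelStack, ms: LabelStack) -> list:
    _require_same_shape(gt, ms)
    return [
        _confusion(gt.labels[z] > 0, ms.labels[z] > 0) for z in range(gt.shape[0])
    ]


def pixel_metrics(c: ConfusionCounts) -> PixelMetrics:
    """Precision, recall and their harmonic mean from voxel tallies."""
    if c.tp == 0:
        if c.fp == 0 and c.fn == 0:
            return PixelMetrics(1.0, 1.0, 1.0)  # both segmentations empty
        return PixelMetrics(0.0, 0.0, 0.0)
    p = c.tp / (c.tp + c.fp)
    r = c.tp / (c.tp + c.fn)
    f = 2.0 * p * r / (p + r)
    return PixelMetrics(p, r, f)


def _overlap_edges(gt_arr: np.ndarray, ms_arr: np.ndarray, min_overlap_fraction: float):
    """Edges (gt_label, ms_label, overlap voxels) of the overlap graph."""
    both = (gt_arr > 0) & (ms_arr > 0)
    if not both.any():
        return []
    pairs = np.stack([gt_arr[both], ms_arr[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    if min_overlap_fraction > 0:
        gt_sizes = np.bincount(gt_arr.ravel())
        kept = []
        for (g, m), n in zip(uniq, counts):
            if n >= min_overlap_fraction * gt_sizes[g]:
                kept.append((int(g), int(m), int(n)))
        return kept
    return [(int(g), int(m), int(n)) for (g, m), n in zip(uniq, counts)]


def _classify(gt_labels: list, ms_labels: list, edges) -> CorrespondenceReport:
    gt_partners = {g: [] for g in gt_labels}
    ms_partners = {m: [] for m in ms_labels}
    for g, m, _ in edges:
        gt_partners[g].append(m)
        ms_partners[m].append(g)
    report = CorrespondenceReport(n_gt_objects=len(gt_labels), n_ms_objects=len(ms_labels))
    for g in gt_labels:
        partners = sorted(gt_partners[g])
        if not partners:
            report.fn_objects.append(g)
        elif len(partners) > 1:
            report.split.append((g, partners))
    for m in ms_labels:
        partners = sorted(ms_partners[m])
        if not partners:
            report.fp_objects.append(m)
        elif len(partners) > 1:
            report.merged.append((m, partners))
    for g in gt_labels:
        if len(gt_partners[g]) == 1:
            m = gt_partners[g][0]
            if len(ms_partners[m]) == 1:
                report.one_to_one.append((g, m))
    return report


def object_correspondence(
    gt: LabelStack, ms: LabelStack, min_overlap_fraction: float = 0.0
) -> CorrespondenceReport:
    """Stack-level object matching via the voxel-overlap bipartite graph.

    Two objects match when they share at least one voxel (or at least the
    configured fraction of the GT object's volume). A GT label with two or
    more MS partners is split; an MS label with two or more GT partners is
    merged; unmatched labels are false-negative GT / false-positive MS.
    """
    _require_same_shape(gt, ms)
    if not (0.0 <= min_overlap_fraction <= 1.0):
        raise ValidationError(f"min overlap fraction must be in [0, 1], got {min_overlap_fraction}")
    edges = _overlap_edges(gt.labels, ms.labels, min_overlap_fraction)
    return _classify(gt.label_set(), ms.label_set(), edges)


def slice_correspondence(
    gt: LabelStack, ms: LabelStack, slice_index: int, min_overlap_fraction: float = 0.0
) -> CorrespondenceReport:
    """Object matching restricted to one slice.

    A slice object is the cross-section of a 3D label on that slice — the
    3D identities are kept, so the report can name which labels merge where.
    """
    _require_same_shape(gt, ms)
    if not (0 <= slice_index < gt.shape[0]):
        raise ValidationError(
            f"slice {slice_index + 1} out of range; stack has {gt.shape[0]} slices"
        )
    gt_sl = gt.labels[slice_index]
    ms_sl = ms.labels[slice_index]
    gt_labels = [int(v) for v in np.unique(gt_sl) if v != 0]
    ms_labels = [int(v) for v in np.unique(ms_sl) if v != 0]
    edges = _overlap_edges(gt_sl, ms_sl, min_overlap_fraction)
    return _classify(gt_labels, ms_labels, edges)


def benchmark_stacks(
    gt: LabelStack, ms: LabelStack, min_overlap_fraction: float = 0.0
) -> BenchmarkReport:
    """Full benchmark: stack-level and per-slice pixel + object evaluation."""
    _require_same_shape(gt, ms)
    stack_conf = confusion_counts(gt, ms)
    slices = []
    for z, conf in enumerate(confusion_counts_per_slice(gt, ms)):
        slices.append(
            SliceBenchmark(
                slice_index=z,
                confusion=conf,
                metrics=pixel_metrics(conf),
                correspondence=slice_correspondence(gt, ms, z, min_overlap_fraction),
            )
        )
    return BenchmarkReport(
        stack_confusion=stack_conf,
        stack_metrics=pixel_metrics(stack_conf),
        stack_correspondence=object_correspondence(gt, ms, min_overlap_fraction),
        slices=slices,
    )


# ---------------------------------------------------------------------------
# report serialisation
# ---------------------------------------------------------------------------

def _join_groups(groups) -> str:
    # entries like "3:1|2" (key label : member labels), ";"-separated
    return ";".join(f"{key}:" + "|".join(str(v) for v in members) for key, members in groups)


def _join_pairs(pairs) -> str:
    return ";".join(f"{g}~{m}" for g, m in pairs)


def _join_labels(labels) -> str:
    return ";".join(str(v) for v in labels)


def _report_column(conf: ConfusionCounts, metrics: PixelMetrics, corr: CorrespondenceReport) -> dict:
    return {
        "n_gt_objects": corr.n_gt_objects,
        "n_ms_objects": corr.n_ms_objects,
        "n_one_to_one": len(corr.one_to_one),
        "one_to_one": _join_pairs(corr.one_to_one),
        "n_merged": len(corr.merged),
        "merged": _join_groups(corr.merged),
        "n_split": len(corr.split),
        "split": _join_groups(corr.split),
        "n_fp_objects": len(corr.fp_objects),
        "fp_objects": _join_labels(corr.fp_objects),
        "n_fn_objects": len(corr.fn_objects),
        "fn_objects": _join_labels(corr.fn_objects),
        "tp": conf.tp,
        "fp": conf.fp,
        "tn": conf.tn,
        "fn": conf.fn,
        "precision": f"{metrics.precision:.6f}",
        "recall": f"{metrics.recall:.6f}",
        "fmeasure": f"{metrics.fmeasure:.6f}",
    }


def write_report_csv(report: BenchmarkReport, path) -> None:
    """Write the benchmark as CSV: one column per slice plus a stack column."""
    columns = [(f"slice_{s.slice_index + 1}", _report_column(s.confusion, s.metrics, s.correspondence))
               for s in report.slices]
    columns.append(
        ("stack", _report_column(report.stack_confusion, report.stack_metrics, report.stack_correspondence))
    )
    measures = list(columns[0][1].keys())
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp.csv")
    os.close(fd)
    try:
        with open(tmp, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["measure"] + [name for name, _ in columns])
            for measure in measures:
                writer.writerow([measure] + [col[measure] for _, col in columns])
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def side_by_side(ms: LabelStack, gt: LabelStack) -> LabelStack:
    """Horizontally combine MS (left) and GT (right) for visual comparison."""
    _require_same_shape(gt, ms)
    combined = np.concatenate([ms.labels, gt.labels], axis=2)
    return LabelStack(labels=combined, calibration=gt.calibration)


# ---------------------------------------------------------------------------
# contour overlay
# ---------------------------------------------------------------------------

def _to_uint8(stack: IntensityStack) -> np.ndarray:
    if stack.bit_depth == 8:
        return stack.voxels.astype(np.uint8)
    return (stack.voxels.astype(np.float64) * (255.0 / stack.max_value)).round().astype(np.uint8)


def region_boundary_2d(mask_slice: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-neighbour outside the region (or the image)."""
    mask_slice = mask_slice.astype(bool)
    cross = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(mask_slice, structure=cross, border_value=0)
    return mask_slice & ~eroded


def overlay_contours(
    stack: IntensityStack, mask: BinaryMask, color=(0, 255, 0)
) -> np.ndarray:
    """RGB copy of the stack with 2D region contours drawn in ``color``."""
    if tuple(stack.shape) != tuple(mask.shape):
        raise ShapeMismatchError(stack.shape, mask.shape, what="stack and mask")
    grey = _to_uint8(stack)
    rgb = np.repeat(grey[..., np.newaxis], 3, axis=3)
    for z in range(stack.shape[0]):
        boundary = region_boundary_2d(mask.mask[z])
        rgb[z][boundary] = color
    return rgb
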