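import csv

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segbench3d.benchmark import (
    ConfusionCounts,
    benchmark_stacks,
    confusion_counts,
    confusion_counts_per_slice,
    object_correspondence,
    overlay_contours,
    pixel_metrics,
    region_boundary_2d,
    side_by_side,
    slice_correspondence,
    write_report_csv,
)
from segbench3d.errors import ShapeMismatchError, ValidationError
from segbench3d.stack_io import BinaryMask, IntensityStack

from conftest import make_labels, make_stack
from oracles import naive_confusion, overlap_edges_bruteforce


def labels_from(arrays):
    """Merge {label: bool array} into one label stack."""
    out = None
    for label, arr in arrays.items():
        arr = np.asarray(arr, dtype=bool)
        if out is None:
            out = np.zeros(arr.shape, dtype=np.int64)
        out[arr] = label
    return make_labels(out)


def ball(shape, centre, radius):
    zz, yy, xx = np.indices(shape)
    cz, cy, cx = centre
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


class TestConfusionCounts:
    def test_identical_stacks(self):
        arr = np.zeros((4, 5, 5), dtype=np.int64)
        arr.reshape(-1)[:30] = 1
        gt = make_labels(arr)
        c = confusion_counts(gt, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (30, 0, 0, 70)

    def test_empty_ms(self):
        arr = np.zeros((4, 5, 5), dtype=np.int64)
        arr.reshape(-1)[:30] = 1
        c = confusion_counts(make_labels(arr), make_labels(np.zeros_like(arr)))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 30, 70)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_bruteforce_tally(self, rng, trial):
        gt = (rng.random((5, 5, 5)) < 0.4).astype(np.int64)
        ms = (rng.random((5, 5, 5)) < 0.4).astype(np.int64)
        c = confusion_counts(make_labels(gt), make_labels(ms))
        assert (c.tp, c.fp, c.tn, c.fn) == naive_confusion(gt > 0, ms > 0)
        assert c.total == 125

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            confusion_counts(
                make_labels(np.zeros((2, 2, 2), dtype=np.int64)),
                make_labels(np.zeros((2, 2, 3), dtype=np.int64)),
            )

    def test_per_slice_sums_to_stack(self, rng):
        gt = make_labels((rng.random((6, 7, 7)) < 0.3).astype(np.int64))
        ms = make_labels((rng.random((6, 7, 7)) < 0.3).astype(np.int64))
        per_slice = confusion_counts_per_slice(gt, ms)
        total = sum(per_slice[1:], per_slice[0])
        assert total == confusion_counts(gt, ms)


class TestPixelMetrics:
    def test_ground_truth_identity(self):
        m = pixel_metrics(ConfusionCounts(tp=30, fp=0, tn=70, fn=0))
        assert (m.precision, m.recall, m.fmeasure) == (1.0, 1.0, 1.0)

    def test_printed_formula_example(self):
        m = pixel_metrics(ConfusionCounts(tp=8, fp=2, tn=0, fn=8))
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.5)
        assert m.fmeasure == pytest.approx(2 * 0.8 * 0.5 / 1.3)

    def test_worst_case_zero(self):
        m = pixel_metrics(ConfusionCounts(tp=0, fp=5, tn=10, fn=5))
        assert (m.precision, m.recall, m.fmeasure) == (0.0, 0.0, 0.0)

    def test_both_empty_is_perfect_agreement(self):
        m = pixel_metrics(ConfusionCounts(tp=0, fp=0, tn=100, fn=0))
        assert (m.precision, m.recall, m.fmeasure) == (1.0, 1.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(tp=st.integers(1, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
    def test_harmonic_mean_bounds(self, tp, fp, fn):
        m = pixel_metrics(ConfusionCounts(tp=tp, fp=fp, tn=0, fn=fn))
        assert min(m.precision, m.recall) - 1e-12 <= m.fmeasure <= max(m.precision, m.recall) + 1e-12
        assert m.fmeasure <= (m.precision + m.recall) / 2 + 1e-12


class TestObjectCorrespondence:
    def test_two_one_to_one(self):
        shape = (10, 16, 16)
        gt = labels_from({1: ball(shape, (4, 4, 4), 2.5), 2: ball(shape, (5, 11, 11), 2.5)})
        corr = object_correspondence(gt, gt)
        assert corr.one_to_one == [(1, 1), (2, 2)]
        assert not (corr.split or corr.merged or corr.fp_objects or corr.fn_objects)

    def test_merged(self):
        shape = (8, 10, 20)
        g1 = ball(shape, (4, 5, 5), 2.5)
        g2 = ball(shape, (4, 5, 14), 2.5)
        gt = labels_from({1: g1, 2: g2})
        ms = labels_from({1: g1 | g2})
        corr = object_correspondence(gt, ms)
        assert corr.merged == [(1, [1, 2])]
        assert corr.one_to_one == []
        edges = overlap_edges_bruteforce(gt.labels, ms.labels)
        assert edges == {(1, 1), (2, 1)}

    def test_split(self):
        shape = (8, 10, 10)
        sphere = ball(shape, (4, 5, 5), 3)
        upper = sphere.copy()
        upper[4:] = False
        lower = sphere & ~upper
        gt = labels_from({1: sphere})
        ms = labels_from({1: upper, 2: lower})
        corr = object_correspondence(gt, ms)
        assert corr.split == [(1, [1, 2])]
        assert corr.merged == []

    def test_fp_and_fn_objects(self):
        shape = (6, 8, 8)
        gt = labels_from({1: ball(shape, (3, 4, 4), 2)})
        ms = labels_from({5: ball(shape, (1, 1, 1), 1)})  # overlaps nothing
        corr = object_correspondence(gt, ms)
        assert corr.fn_objects == [1]
        assert corr.fp_objects == [5]

    def test_min_overlap_fraction(self):
        shape = (4, 4, 8)
        g = np.zeros(shape, dtype=bool)
        g[1, 1, 0:4] = True  # 4 voxels
        m = np.zeros(shape, dtype=bool)
        m[1, 1, 3:6] = True  # overlap = 1 voxel = 25% of GT
        gt, ms = labels_from({1: g}), labels_from({1: m})
        assert object_correspondence(gt, ms, min_overlap_fraction=0.0).one_to_one == [(1, 1)]
        assert object_correspondence(gt, ms, min_overlap_fraction=0.5).fn_objects == [1]

    def test_bad_fraction(self):
        gt = make_labels(np.zeros((2, 2, 2), dtype=np.int64))
        with pytest.raises(ValidationError):
            object_correspondence(gt, gt, min_overlap_fraction=1.5)

    def test_exhaustiveness_invariant(self, rng):
        # every label lands in at least one bucket; one-to-one labels in exactly one
        gt_arr = rng.integers(0, 4, size=(6, 8, 8)).astype(np.int64)
        ms_arr = rng.integers(0, 4, size=(6, 8, 8)).astype(np.int64)
        gt, ms = make_labels(gt_arr), make_labels(ms_arr)
        corr = object_correspondence(gt, ms)
        gt_seen = (
            {g for g, _ in corr.one_to_one}
            | {g for g, _ in corr.split}
            | {g for _, gs in corr.merged for g in gs}
            | set(corr.fn_objects)
        )
        ms_seen = (
            {m for _, m in corr.one_to_one}
            | {m for m, _ in corr.merged}
            | {m for _, ms_list in corr.split for m in ms_list}
            | set(corr.fp_objects)
        )
        assert gt_seen == set(gt.label_set())
        assert ms_seen == set(ms.label_set())


class TestSwapSymmetry:
    def test_swap_exchanges_roles(self, rng):
        gt = make_labels(rng.integers(0, 3, size=(5, 9, 9)).astype(np.int64))
        ms = make_labels(rng.integers(0, 3, size=(5, 9, 9)).astype(np.int64))
        fwd, rev = benchmark_stacks(gt, ms), benchmark_stacks(ms, gt)
        assert fwd.stack_metrics.precision == pytest.approx(rev.stack_metrics.recall)
        assert fwd.stack_metrics.recall == pytest.approx(rev.stack_metrics.precision)
        assert fwd.stack_metrics.fmeasure == pytest.approx(rev.stack_metrics.fmeasure)
        assert fwd.stack_confusion.fp == rev.stack_confusion.fn
        assert fwd.stack_confusion.fn == rev.stack_confusion.fp
        assert fwd.stack_correspondence.split == rev.stack_correspondence.merged
        assert fwd.stack_correspondence.merged == rev.stack_correspondence.split
        assert fwd.stack_correspondence.fp_objects == rev.stack_correspondence.fn_objects
        assert fwd.stack_correspondence.fn_objects == rev.stack_correspondence.fp_objects


def _bridge_pair():
    """GT: two spheres overlapping in z only on slices 10-12 (1-based).

    MS: both spheres plus a connecting bridge -> one single 3D label.
    """
    shape = (20, 24, 24)
    g1 = ball(shape, (8, 8, 12), 3.4)  # z extent 5..11 (0-based)
    g2 = ball(shape, (12, 16, 12), 3.4)  # z extent 9..15
    bridge = np.zeros(shape, dtype=bool)
    bridge[9:12, 11:14, 12] = True
    gt = labels_from({1: g1, 2: g2})
    ms = labels_from({1: g1 | g2 | bridge})
    return gt, ms


class TestSliceCorrespondence:
    def test_merge_localised_to_bridge_slices(self):
        gt, ms = _bridge_pair()
        merged_slices = []
        for z in range(gt.shape[0]):
            corr = slice_correspondence(gt, ms, z)
            if corr.merged:
                merged_slices.append(z + 1)
        assert merged_slices == [10, 11, 12]

    def test_empty_slice(self):
        gt, ms = _bridge_pair()
        corr = slice_correspondence(gt, ms, 0)
        assert corr.n_gt_objects == corr.n_ms_objects == 0
        assert not (corr.one_to_one or corr.merged or corr.split or corr.fp_objects or corr.fn_objects)

    def test_extra_speck_is_slice_fp(self):
        shape = (6, 10, 10)
        g = ball(shape, (3, 5, 5), 2)
        gt = labels_from({1: g})
        ms_arr = np.where(g, 1, 0).astype(np.int64)
        ms_arr[0, 0, 0] = 9
        corr = slice_correspondence(gt, make_labels(ms_arr), 0)
        assert corr.fp_objects == [9]

    def test_slice_out_of_range(self):
        gt, ms = _bridge_pair()
        with pytest.raises(ValidationError):
            slice_correspondence(gt, ms, 99)


class TestBenchmarkReport:
    def test_gt_against_itself_all_ones(self):
        gt, _ = _bridge_pair()
        report = benchmark_stacks(gt, gt)
        m = report.stack_metrics
        assert (m.precision, m.recall, m.fmeasure) == (1.0, 1.0, 1.0)
        for s in report.slices:
            assert (s.metrics.precision, s.metrics.recall, s.metrics.fmeasure) == (1.0, 1.0, 1.0)
            assert not (s.correspondence.merged or s.correspondence.split)

    def test_slice_counts_sum_to_stack(self):
        gt, ms = _bridge_pair()
        report = benchmark_stacks(gt, ms)
        assert sum(s.confusion.tp for s in report.slices) == report.stack_confusion.tp
        assert sum(s.confusion.fp for s in report.slices) == report.stack_confusion.fp
        assert sum(s.confusion.tn for s in report.slices) == report.stack_confusion.tn
        assert sum(s.confusion.fn for s in report.slices) == report.stack_confusion.fn

    def test_csv_layout_one_column_per_slice(self, tmp_path):
        Z = 68
        gt = make_labels(np.zeros((Z, 4, 4), dtype=np.int64))
        report = benchmark_stacks(gt, gt)
        path = tmp_path / "report.csv"
        write_report_csv(report, path)
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        header = rows[0]
        assert header[0] == "measure"
        assert header[1:] == [f"slice_{i}" for i in range(1, Z + 1)] + ["stack"]
        measures = [row[0] for row in rows[1:]]
        for name in ("n_gt_objects", "n_ms_objects", "merged", "split", "fp_objects",
                     "fn_objects", "tp", "fp", "tn", "fn", "precision", "recall", "fmeasure"):
            assert name in measures

    def test_csv_merged_cell_lists_labels(self, tmp_path):
        gt, ms = _bridge_pair()
        path = tmp_path / "report.csv"
        write_report_csv(benchmark_stacks(gt, ms), path)
        with open(path, newline="") as fh:
            rows = {row[0]: row[1:] for row in csv.reader(fh)}
        stack_col = -1
        assert rows["merged"][stack_col] == "1:1|2"
        assert rows["n_merged"][stack_col] == "1"

    def test_side_by_side(self):
        gt, ms = _bridge_pair()
        combined = side_by_side(ms, gt)
        Z, H, W = gt.shape
        assert combined.shape == (Z, H, 2 * W)
        assert np.array_equal(combined.labels[:, :, :W], ms.labels)
        assert np.array_equal(combined.labels[:, :, W:], gt.labels)


class TestOverlay:
    def test_empty_mask_replicates_grayscale(self, random_stack):
        mask = BinaryMask(mask=np.zeros(random_stack.shape, dtype=np.uint8))
        rgb = overlay_contours(random_stack, mask)
        assert rgb.shape == random_stack.shape + (3,)
        for c in range(3):
            assert np.array_equal(rgb[..., c], random_stack.voxels)

    def test_square_boundary_pixel_count(self):
        mask_slice = np.zeros((9, 9), dtype=np.uint8)
        mask_slice[2:7, 2:7] = 1  # 5x5 square
        assert int(region_boundary_2d(mask_slice).sum()) == 16

    def test_full_slice_boundary_is_border_ring(self):
        boundary = region_boundary_2d(np.ones((6, 8), dtype=np.uint8))
        expected = np.zeros((6, 8), dtype=bool)
        expected[0] = expected[-1] = True
        expected[:, 0] = expected[:, -1] = True
        assert np.array_equal(boundary, expected)

    def test_contour_colour_applied(self):
        voxels = np.zeros((1, 9, 9), dtype=np.uint8)
        stack = make_stack(voxels)
        mask_arr = np.zeros((1, 9, 9), dtype=np.uint8)
        mask_arr[0, 2:7, 2:7] = 1
        rgb = overlay_contours(stack, BinaryMask(mask=mask_arr))
        boundary = region_boundary_2d(mask_arr[0])
        assert (rgb[0][boundary] == np.array([0, 255, 0])).all()
        assert (rgb[0][~boundary] == 0).all()

    def test_shape_mismatch(self, random_stack):
        mask = BinaryMask(mask=np.zeros((1, 2, 2), dtype=np.uint8))
        with pytest.raises(ShapeMismatchError):
            overlay_contours(random_stack, mask)

    def test_16bit_scaled_to_8bit_range(self):
        voxels = np.full((1, 4, 4), 65535, dtype=np.uint16)
        stack = make_stack(voxels, bit_depth=16)
        rgb = overlay_contours(stack, BinaryMask(mask=np.zeros((1, 4, 4), dtype=np.uint8)))
        assert rgb.max() == 255
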