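# segbench3d

Ground-truth creation and quantitative benchmarking for threshold-based
segmentation of 3D grayscale microscopy stacks.

The package covers a complete desk-scale workflow:

* **I/O** — calibrated multi-page TIFF stacks (8/16-bit grayscale, 16/32-bit
  labels) plus CSV sidecars for seeds, wand-ROI parameters, object statistics
  and benchmark reports (`segbench3d.stack_io`).
* **Preprocessing** — slice-wise square median filtering (`segbench3d.preprocess`).
* **Auto-thresholding** — six global histogram methods: Otsu, IsoData
  (Ridler–Calvard), Li (iterative minimum cross entropy), Huang (minimum
  fuzziness), Yen and the three-order Rényi-entropy combination
  (`segbench3d.autothreshold`). Foreground rule: intensity > θ.
* **Segmentation** — global interval thresholding, wand-style 2D ROIs
  (rightward scan + filled 8-connected component), seeded 3D
  connected-threshold region growing, and dual-threshold depth-compensated
  segmentation driven by a demarcation slice (`segbench3d.segment`).
* **Labelling & volumetry** — 2D/3D connected components (4/8 and 6/18/26
  connectivity) with deterministic raster-order labels, per-object voxel
  counts, calibrated volumes in µm³ and centroids (`segbench3d.labelling`).
* **Benchmarking** — pixel-level precision/recall/F-measure and object-level
  one-to-one / split / merged / false-positive / false-negative
  correspondence between a machine segmentation (MS) and a ground truth
  (GT), per stack *and* per slice (slice objects are cross-sections of the
  3D labels, so reports name exactly which labels merge on which slice);
  CSV reports with one column per slice, side-by-side MS|GT visual stacks
  and RGB contour overlays (`segbench3d.benchmark`).
* **Phantoms** — a deterministic generator of calibrated synthetic stacks
  with exactly known ground truth (ellipsoidal nuclei, haze, attached
  droplet blobs, depth attenuation, read noise) and six named fixtures used
  throughout the test suite (`segbench3d.synth`).

## Test

```sh
python -m pytest -q tests/
```

The suite checks every operation against independent brute-force oracles
(BFS flood fill, naive sliding-window medians, exhaustive criterion scans)
and property-tests the documented invariants.

## CLI

One subcommand per pipeline stage:

```sh
segbench3d phantom --fixture merge-bridge --out fx/       # synthetic data
segbench3d smooth --radius 3 fx/image.tif smooth.tif
segbench3d autothresh --method otsu --apply mask.tif smooth.tif
segbench3d label --connectivity 26 mask.tif ms_labels.tif
segbench3d grow --seeds fx/seeds.csv --tmin 120 fx/image.tif gt_labels.tif
segbench3d dual --seeds fx/seeds.csv --shallow 80 --deep 55 --zsep 12 in.tif gt.tif
segbench3d slices --params rois.csv --radius 3 in.tif gt.tif
segbench3d stats gt_labels.tif --out stats.csv
segbench3d bench --gt gt_labels.tif --ms ms_labels.tif --out report.csv --visual sbs.tif
segbench3d overlay --mask mask.tif fx/image.tif contours_rgb.tif
```

Exit codes: 0 success, 1 validation/data error (one-line message on
stderr), 2 usage error. Slice numbers in all CSV files are 1-based
(ImageJ convention); in-memory indices are 0-based `[z][y][x]`.

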