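"""Calibrated stack and sidecar-file input/output.

Stacks are multi-page grayscale TIFFs; page 0 is slice 0. In memory all
arrays are indexed ``[z][y][x]`` with 0-based coordinates. Human-facing CSV
files (seeds, ROI parameters, reports) use 1-based slice numbers, matching
the ImageJ convention; x/y pixel coordinates stay 0-based in both worlds.

Calibration (micrometres per voxel edge) is read from the TIFF resolution
tags and, for z spacing, from ImageJ-style metadata when present. A missing
calibration falls back to 1.0 um isotropic with a logged warning — pixel
benchmarking does not need it, volumetry does.
"""

from __future__ import annotations

import csv
import logging
import os
import tempfile
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
import tifffile

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelCalibration",
    "IntensityStack",
    "LabelStack",
    "BinaryMask",
    "SeedRecord",
    "RoiParams",
    "read_intensity_stack",
    "write_intensity_stack",
    "read_label_stack",
    "write_label_stack",
    "read_binary_mask",
    "write_binary_mask",
    "write_rgb_stack",
    "read_seeds",
    "write_seeds",
    "read_roi_params",
    "write_roi_params",
]


@dataclass(frozen=True)
class VoxelCalibration:
    """Physical voxel edge lengths in micrometres."""

    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0

    def __post_init__(self):
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValidationError(
                f"voxel calibration must be strictly positive, got "
                f"({self.dx}, {self.dy}, {self.dz})"
            )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        return self.dx * self.dy * self.dz


DEFAULT_CALIBRATION = VoxelCalibration(1.0, 1.0, 1.0)


@dataclass
class IntensityStack:
    """A 3D grayscale image: non-negative integers, 8- or 16-bit."""

    voxels: np.ndarray
    bit_depth: int
    calibration: VoxelCalibration = field(default_factory=VoxelCalibration)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"intensity stack must be 3D, got shape {self.voxels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if self.voxels.size and int(self.voxels.max()) > self.max_value:
            raise ValidationError(
                f"voxel value {int(self.voxels.max())} exceeds {self.bit_depth}-bit range"
            )
        if self.voxels.size and int(self.voxels.min()) < 0:
            raise ValidationError("intensity voxels must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def max_value(self) -> int:
        """Largest representable intensity for this bit depth."""
        return (1 << self.bit_depth) - 1


@dataclass
class LabelStack:
    """A labelled 3D image: 0 = background, k > 0 = object k."""

    labels: np.ndarray
    calibration: VoxelCalibration = field(default_factory=VoxelCalibration)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"label stack must be 3D, got shape {self.labels.shape}")
        if self.labels.size and int(self.labels.min()) < 0:
            raise ValidationError("labels must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def label_set(self) -> list:
        """Sorted distinct non-zero labels."""
        values = np.unique(self.labels)
        return [int(v) for v in values if v != 0]


@dataclass
class BinaryMask:
    """A 0/1 foreground mask over a 3D stack."""

    mask: np.ndarray
    calibration: VoxelCalibration = field(default_factory=VoxelCalibration)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValidationError(f"mask must be 3D, got shape {self.mask.shape}")
        bad = np.setdiff1d(np.unique(self.mask), [0, 1])
        if bad.size:
            raise ValidationError(f"mask values must be 0/1, found {bad.tolist()}")
        self.mask = self.mask.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple:
        return self.mask.shape


@dataclass(frozen=True)
class SeedRecord:
    """One region-growing seed: 0-based voxel coordinates plus object id."""

    object_id: int
    x: int
    y: int
    z: int

    def __post_init__(self):
        if self.object_id <= 0:
            raise ValidationError(f"objectId must be positive, got {self.object_id}")


@dataclass(frozen=True)
class RoiParams:
    """A wand ROI record: start point plus intensity window on one slice.

    ``slice_index`` is 0-based in memory; CSV files carry it 1-based.
    ``theta_max`` of ``None`` means "resolve to the bit-depth maximum when
    applied".
    """

    object_id: int
    slice_index: int
    start_x: int
    start_y: int
    theta_min: int
    theta_max: Optional[int] = None

    def __post_init__(self):
        if self.object_id <= 0:
            raise ValidationError(f"objectId must be positive, got {self.object_id}")
        if self.theta_max is not None and self.theta_min > self.theta_max:
            raise ValidationError(
                f"thetaMin {self.theta_min} > thetaMax {self.theta_max} "
                f"(object {self.object_id}, slice {self.slice_index + 1})"
            )

    def resolve_theta_max(self, bit_depth: int) -> int:
        return self.theta_max if self.theta_max is not None else (1 << bit_depth) - 1


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def _atomic_write(path, write_fn):
    """Write via a temp file in the target directory, then rename."""
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp.tif")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _resolution_kwargs(calibration: VoxelCalibration) -> dict:
    xres = Fraction(1.0 / calibration.dx).limit_denominator(10**9)
    yres = Fraction(1.0 / calibration.dy).limit_denominator(10**9)
    return {
        "resolution": ((xres.numerator, xres.denominator), (yres.numerator, yres.denominator)),
        "metadata": {"spacing": calibration.dz, "unit": "um", "axes": "ZYX"},
    }


def _stack_metadata(tif: tifffile.TiffFile) -> dict:
    """Spacing/unit metadata: ImageJ block or the shaped-JSON description."""
    if tif.imagej_metadata:
        return tif.imagej_metadata
    description = tif.pages[0].description or ""
    if description.startswith("{"):
        import json

        try:
            parsed = json.loads(description)
        except ValueError:
            return {}
        if isinstance(parsed, dict):
            return parsed
    return {}


def _read_calibration(tif: tifffile.TiffFile) -> Optional[VoxelCalibration]:
    metadata = _stack_metadata(tif)
    # A bare default XResolution of (1, 1) with no unit means "uncalibrated";
    # we require explicit unit/spacing metadata, as our own writers emit.
    if "spacing" not in metadata and "unit" not in metadata:
        return None
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None:
        return None
    try:
        dx = float(Fraction(*xres.value) ** -1)
        dy = float(Fraction(*yres.value) ** -1)
    except ZeroDivisionError:
        return None
    dz = float(metadata.get("spacing", 1.0))
    if dx <= 0 or dy <= 0 or dz <= 0:
        return None
    return VoxelCalibration(dx=dx, dy=dy, dz=dz)


def _load_pages(tif: tifffile.TiffFile, path) -> np.ndarray:
    series = tif.series[0]
    if "S" in series.axes:
        raise FormatError(f"{path}: multi-sample (RGB/multichannel) TIFF is not grayscale")
    data = series.asarray()
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    return data


def read_intensity_stack(path, calibration_override: Optional[VoxelCalibration] = None) -> IntensityStack:
    """Read a multi-page 8/16-bit grayscale TIFF.

    Calibration comes from the file's resolution tags (plus ImageJ z
    spacing) unless ``calibration_override`` is given, which always wins.
    With neither, 1.0 um isotropic is assumed and a warning is logged.
    """
    try:
        tif = tifffile.TiffFile(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    with tif:
        data = _load_pages(tif, path)
        calibration = _read_calibration(tif)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got array shape {data.shape}")
    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(
            f"{path}: unsupported pixel type {data.dtype}; only 8- and 16-bit grayscale "
            "TIFF stacks are readable"
        )
    if calibration_override is not None:
        calibration = calibration_override
    elif calibration is None:
        logger.warning("%s: no voxel calibration in TIFF tags; assuming 1.0 um isotropic", path)
        calibration = DEFAULT_CALIBRATION
    return IntensityStack(voxels=data, bit_depth=bit_depth, calibration=calibration)


def write_intensity_stack(stack: IntensityStack, path) -> None:
    """Write a stack as an ImageJ-compatible multi-page TIFF with calibration."""
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    data = stack.voxels.astype(dtype, copy=False)
    kwargs = _resolution_kwargs(stack.calibration)
    _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, data, imagej=True, **kwargs))


def read_label_stack(path, calibration_override: Optional[VoxelCalibration] = None) -> LabelStack:
    """Read an integer-valued labelled stack (8/16/32-bit unsigned TIFF)."""
    try:
        tif = tifffile.TiffFile(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    with tif:
        data = _load_pages(tif, path)
        calibration = _read_calibration(tif)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected single-channel label pages, got shape {data.shape}")
    if data.dtype not in (np.uint8, np.uint16, np.uint32, np.int16, np.int32):
        raise FormatError(f"{path}: unsupported label pixel type {data.dtype}")
    if data.size and int(data.min()) < 0:
        raise FormatError(f"{path}: negative values are not valid labels")
    if calibration_override is not None:
        calibration = calibration_override
    elif calibration is None:
        calibration = DEFAULT_CALIBRATION
    return LabelStack(labels=data.astype(np.int64), calibration=calibration)


def write_label_stack(labels: LabelStack, path) -> None:
    """Write a labelled stack: 16-bit when labels fit, 32-bit otherwise."""
    data = labels.labels
    if data.size and int(data.min()) < 0:
        raise ValidationError("negative labels cannot be serialised")
    max_label = int(data.max()) if data.size else 0
    kwargs = _resolution_kwargs(labels.calibration)
    if max_label <= 0xFFFF:
        out = data.astype(np.uint16)
        _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, out, imagej=True, **kwargs))
    else:
        out = data.astype(np.uint32)
        # ImageJ hyperstack format does not take uint32; plain TIFF keeps the tags.
        _atomic_write(
            path, lambda tmp: tifffile.imwrite(tmp, out, photometric="minisblack", **kwargs)
        )


def read_binary_mask(path, calibration_override: Optional[VoxelCalibration] = None) -> BinaryMask:
    """Read a mask stack; any non-zero pixel counts as foreground."""
    lab = read_label_stack(path, calibration_override)
    return BinaryMask(mask=(lab.labels > 0).astype(np.uint8), calibration=lab.calibration)


def write_binary_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit TIFF with foreground 255 (ImageJ binary style)."""
    data = (mask.mask > 0).astype(np.uint8) * 255
    kwargs = _resolution_kwargs(mask.calibration)
    _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, data, imagej=True, **kwargs))


def write_rgb_stack(rgb: np.ndarray, calibration: VoxelCalibration, path) -> None:
    """Write a (Z, H, W, 3) uint8 RGB stack."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 4 or rgb.shape[-1] != 3 or rgb.dtype != np.uint8:
        raise ValidationError(f"RGB stack must be (Z, H, W, 3) uint8, got {rgb.shape} {rgb.dtype}")
    xres = Fraction(1.0 / calibration.dx).limit_denominator(10**9)
    yres = Fraction(1.0 / calibration.dy).limit_denominator(10**9)
    kwargs = {
        "resolution": ((xres.numerator, xres.denominator), (yres.numerator, yres.denominator)),
        "photometric": "rgb",
    }
    _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, rgb, **kwargs))


# ---------------------------------------------------------------------------
# CSV sidecars
# ---------------------------------------------------------------------------

def _int_field(value: str, name: str, row_number: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_number}: {name} must be an integer, got {value!r}")


def read_seeds(path) -> list:
    """Read seed records from CSV.

    Accepts a headered ``objectId,x,y,z`` file or a headerless 3-column
    ``x,y,z`` file whose rows get ids 1..n in order. The z column is a
    1-based slice number on disk and is converted to 0-based here.
    """
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(cell.strip() for cell in row)]
    if not rows:
        return []
    header = [cell.strip().lower() for cell in rows[0]]
    seeds = []
    if "objectid" in header or header[:3] == ["x", "y", "z"]:
        has_id = "objectid" in header
        col = {name: i for i, name in enumerate(header)}
        body = rows[1:]
        for n, row in enumerate(body, start=2):
            oid = _int_field(row[col["objectid"]], "objectId", n) if has_id else len(seeds) + 1
            seeds.append(
                SeedRecord(
                    object_id=oid,
                    x=_int_field(row[col["x"]], "x", n),
                    y=_int_field(row[col["y"]], "y", n),
                    z=_int_field(row[col["z"]], "z", n) - 1,
                )
            )
    else:
        for n, row in enumerate(rows, start=1):
            if len(row) == 3:
                x, y, z = (_int_field(v, name, n) for v, name in zip(row, ("x", "y", "z")))
                seeds.append(SeedRecord(object_id=len(seeds) + 1, x=x, y=y, z=z - 1))
            elif len(row) == 4:
                oid = _int_field(row[0], "objectId", n)
                x = _int_field(row[1], "x", n)
                y = _int_field(row[2], "y", n)
                z = _int_field(row[3], "z", n)
                seeds.append(SeedRecord(object_id=oid, x=x, y=y, z=z - 1))
            else:
                raise ValidationError(f"row {n}: expected 3 or 4 columns, got {len(row)}")
    ids = [s.object_id for s in seeds]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate objectId values in {path}: {dupes}")
    return seeds


def write_seeds(seeds: Iterable[SeedRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["objectId", "x", "y", "z"])
        for seed in seeds:
            writer.writerow([seed.object_id, seed.x, seed.y, seed.z + 1])


def read_roi_params(path) -> list:
    """Read wand ROI parameter rows from CSV.

    Header: ``objectId,slice,startX,startY,thetaMin,thetaMax``. An empty
    thetaMax cell means "bit-depth maximum, resolved at use time". Slice
    numbers are 1-based on disk.
    """
    params = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        fields = {name.strip().lower(): name for name in reader.fieldnames}
        required = ["objectid", "slice", "startx", "starty", "thetamin"]
        missing = [name for name in required if name not in fields]
        if missing:
            raise ValidationError(f"{path}: missing ROI columns {missing}")
        for n, row in enumerate(reader, start=2):
            theta_max_raw = row.get(fields.get("thetamax", ""), "")
            theta_max = None
            if theta_max_raw is not None and str(theta_max_raw).strip() != "":
                theta_max = _int_field(theta_max_raw, "thetaMax", n)
            try:
                params.append(
                    RoiParams(
                        object_id=_int_field(row[fields["objectid"]], "objectId", n),
                        slice_index=_int_field(row[fields["slice"]], "slice", n) - 1,
                        start_x=_int_field(row[fields["startx"]], "startX", n),
                        start_y=_int_field(row[fields["starty"]], "startY", n),
                        theta_min=_int_field(row[fields["thetamin"]], "thetaMin", n),
                        theta_max=theta_max,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {n}: {exc}") from exc
    return params


def write_roi_params(params: Sequence[RoiParams], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["objectId", "slice", "startX", "startY", "thetaMin", "thetaMax"])
        for p in params:
            writer.writerow(
                [
                    p.object_id,
                    p.slice_index + 1,
                    p.start_x,
                    p.start_y,
                    p.theta_min,
                    "" if p.theta_max is None else p.theta_max,
                ]
            )
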