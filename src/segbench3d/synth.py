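"""Synthetic calibrated phantoms with exactly known ground truth.

Phantoms emulate the imaging obstacles of fluorescence nuclei stacks:
bright ellipsoidal nuclei, a haze of diffuse signal hugging them, small
bright blobs attached to objects, depth-dependent signal attenuation and
read noise. The truth labelling is derived from the noiseless,
unattenuated per-nucleus field only, so it stays a gold standard no matter
how badly the image is corrupted.

Rendering profile: each primitive is a plateau (full intensity inside the
unit ellipsoid) with a smooth Gaussian rim that starts at ``rim_factor``
times the peak. The drop at the plateau edge guarantees an intensity gap
between an object and its rim, which makes the fixtures' expected voxel
sets exactly computable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .stack_io import IntensityStack, LabelStack, SeedRecord, VoxelCalibration


@dataclass(frozen=True)
class Nucleus:
    centre: tuple  # (z, y, x), may be fractional
    radii: tuple  # (rz, ry, rx) in voxels
    peak: float


@dataclass(frozen=True)
class Droplet:
    centre: tuple  # (z, y, x)
    radius: float
    intensity: float


@dataclass
class PhantomSpec:
    shape: tuple  # (Z, H, W)
    bit_depth: int = 8
    calibration: VoxelCalibration = field(default_factory=VoxelCalibration)
    nuclei: Sequence[Nucleus] = ()
    haze: float = 0.0  # amplitude of diffuse signal hugging each nucleus
    droplets: Sequence[Droplet] = ()
    attenuation: float = 0.0  # per-slice decay: intensity * exp(-alpha * z)
    noise_sigma: float = 0.0
    iso_level: int = 120  # intensity defining the true object surface
    rim_factor: float = 0.5  # rim starts at rim_factor * peak just outside the plateau
    rim_width: float = 0.15  # Gaussian width of the rim, in units of d
    rng_seed: int = 0

    def __post_init__(self):
        self.shape = tuple(self.shape)
        self.nuclei = tuple(self.nuclei)
        self.droplets = tuple(self.droplets)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValidationError(f"phantom shape must be 3 positive ints, got {self.shape}")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        for nucleus in self.nuclei:
            if nucleus.peak * self.rim_factor >= self.iso_level:
                raise ValidationError(
                    "rim intensity must stay below iso_level so the truth surface is "
                    f"unambiguous (peak {nucleus.peak}, rim_factor {self.rim_factor}, "
                    f"iso {self.iso_level})"
                )
        if self.haze >= self.iso_level:
            raise ValidationError("haze amplitude must stay below iso_level")


@dataclass
class Phantom:
    image: IntensityStack
    truth: LabelStack
    spec: PhantomSpec

    def seeds(self) -> list:
        """One seed per nucleus at its (rounded) centre, ids 1..n."""
        out = []
        for k, nucleus in enumerate(self.spec.nuclei, start=1):
            cz, cy, cx = (int(round(c)) for c in nucleus.centre)
            out.append(SeedRecord(object_id=k, x=cx, y=cy, z=cz))
        return out


def _ellipsoid_distance(shape, centre, radii) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=np.float64)
    cz, cy, cx = centre
    rz, ry, rx = radii
    return np.sqrt(((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)


def _profile(d: np.ndarray, peak: float, rim_factor: float, rim_width: float) -> np.ndarray:
    rim = rim_factor * peak * np.exp(-(((d - 1.0) / rim_width) ** 2))
    return np.where(d <= 1.0, peak, rim)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom; deterministic for a given ``spec.rng_seed``.

    Truth label k is exactly the voxel set where nucleus k's noiseless,
    unattenuated field rounds to at least ``iso_level``. Truth regions of
    different nuclei must be disjoint.
    """
    rng = np.random.default_rng(spec.rng_seed)
    Z, H, W = spec.shape
    combined = np.zeros(spec.shape, dtype=np.float64)
    truth = np.zeros(spec.shape, dtype=np.int64)

    for k, nucleus in enumerate(spec.nuclei, start=1):
        d = _ellipsoid_distance(spec.shape, nucleus.centre, nucleus.radii)
        fld = _profile(d, nucleus.peak, spec.rim_factor, spec.rim_width)
        region = np.rint(fld) >= spec.iso_level
        clash = region & (truth != 0)
        if clash.any():
            zc, yc, xc = (int(v[0]) for v in np.nonzero(clash))
            raise ValidationError(
                f"truth regions of nuclei {int(truth[zc, yc, xc])} and {k} collide at "
                f"(x={xc}, y={yc}, z={zc}); place nuclei disjointly"
            )
        truth[region] = k
        np.maximum(combined, fld, out=combined)
        if spec.haze > 0:
            haze = spec.haze * np.exp(-((d / 2.2) ** 2))
            np.maximum(combined, haze, out=combined)

    for droplet in spec.droplets:
        d = _ellipsoid_distance(spec.shape, droplet.centre, (droplet.radius,) * 3)
        fld = _profile(d, droplet.intensity, spec.rim_factor, spec.rim_width)
        np.maximum(combined, fld, out=combined)

    if spec.attenuation != 0.0:
        decay = np.exp(-spec.attenuation * np.arange(Z, dtype=np.float64))
        combined = combined * decay[:, np.newaxis, np.newaxis]
    if spec.noise_sigma > 0:
        combined = combined + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    max_value = (1 << spec.bit_depth) - 1
    image = np.clip(np.rint(combined), 0, max_value)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return Phantom(
        image=IntensityStack(
            voxels=image.astype(dtype), bit_depth=spec.bit_depth, calibration=spec.calibration
        ),
        truth=LabelStack(labels=truth, calibration=spec.calibration),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

_CAL = VoxelCalibration(0.5, 0.5, 1.0)

#: Dual-threshold parameters that exactly recover the deep-attenuated fixture.
DEEP_ATTENUATED_PARAMS = {"theta_shallow": 80, "theta_deep": 55, "demarcation_slice": 12}

#: 1-based slices on which the merge-bridge fixture's GT objects coexist.
MERGE_BRIDGE_SLICES = (10, 11, 12)

FIXTURE_NAMES = (
    "clean-nuclei",
    "attached-droplet",
    "free-histone",
    "low-contrast",
    "deep-attenuated",
    "merge-bridge",
)


def _fixture_spec(name: str) -> PhantomSpec:
    if name == "clean-nuclei":
        return PhantomSpec(
            shape=(20, 48, 48),
            calibration=_CAL,
            nuclei=[
                Nucleus(centre=(6, 12, 12), radii=(3.5, 5.0, 5.0), peak=200),
                Nucleus(centre=(9, 32, 14), radii=(3.0, 4.5, 4.5), peak=200),
                Nucleus(centre=(13, 22, 34), radii=(3.5, 5.5, 5.5), peak=200),
            ],
            rng_seed=101,
        )
    if name == "attached-droplet":
        return PhantomSpec(
            shape=(16, 40, 40),
            calibration=_CAL,
            nuclei=[Nucleus(centre=(8, 20, 16), radii=(3.5, 6.0, 6.0), peak=200)],
            droplets=[Droplet(centre=(8, 20, 24), radius=2.0, intensity=150)],
            rng_seed=102,
        )
    if name == "free-histone":
        return PhantomSpec(
            shape=(16, 40, 40),
            calibration=_CAL,
            nuclei=[Nucleus(centre=(8, 20, 20), radii=(3.0, 5.0, 5.0), peak=200)],
            haze=80.0,
            noise_sigma=3.0,
            rng_seed=103,
        )
    if name == "low-contrast":
        return PhantomSpec(
            shape=(16, 40, 40),
            calibration=_CAL,
            nuclei=[Nucleus(centre=(8, 20, 20), radii=(3.0, 5.5, 5.5), peak=200)],
            haze=110.0,
            noise_sigma=4.0,
            rng_seed=104,
        )
    if name == "deep-attenuated":
        return PhantomSpec(
            shape=(28, 40, 40),
            calibration=_CAL,
            nuclei=[
                Nucleus(centre=(6, 20, 20), radii=(3.5, 5.5, 5.5), peak=200),
                Nucleus(centre=(20, 20, 20), radii=(3.5, 5.5, 5.5), peak=200),
            ],
            attenuation=0.05,
            rim_factor=0.25,
            rng_seed=105,
        )
    if name == "merge-bridge":
        return PhantomSpec(
            shape=(21, 40, 40),
            calibration=_CAL,
            nuclei=[
                Nucleus(centre=(7, 14, 20), radii=(4.0, 6.0, 6.0), peak=200),
                Nucleus(centre=(13, 26, 20), radii=(4.0, 6.0, 6.0), peak=200),
            ],
            droplets=[
                Droplet(centre=(9, 18, 20), radius=1.2, intensity=150),
                Droplet(centre=(10, 20, 20), radius=1.2, intensity=150),
                Droplet(centre=(11, 22, 20), radius=1.2, intensity=150),
            ],
            rng_seed=106,
        )
    raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def standard_fixture(name: str) -> Phantom:
    """Generate one of the named deterministic fixtures."""
    return generate_phantom(_fixture_spec(name))


def standard_fixtures() -> dict:
    """All named fixtures, keyed by name."""
    return {name: standard_fixture(name) for name in FIXTURE_NAMES}


def spec_to_json(spec: PhantomSpec) -> str:
    payload = asdict(spec)
    payload["calibration"] = asdict(spec.calibration)
    payload["nuclei"] = [asdict(n) for n in spec.nuclei]
    payload["droplets"] = [asdict(d) for d in spec.droplets]
    return json.dumps(payload, indent=2)


def spec_from_json(text: str) -> PhantomSpec:
    payload = json.loads(text)
    payload["calibration"] = VoxelCalibration(**payload["calibration"])
    payload["nuclei"] = [Nucleus(centre=tuple(n["centre"]), radii=tuple(n["radii"]), peak=n["peak"])
                         for n in payload["nuclei"]]
    payload["droplets"] = [
        Droplet(centre=tuple(d["centre"]), radius=d["radius"], intensity=d["intensity"])
        for d in payload["droplets"]
    ]
    payload["shape"] = tuple(payload["shape"])
    return PhantomSpec(**payload)
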