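"""Synthetic TOF-MRA-like phantoms with circle-of-Willis topology.

The phantom emulates what the path-finding methods actually consume: bright
tubular arteries on a dark background, wired with the CoW's loop topology
(AComm closing the anterior circulation, PComms joining anterior and
posterior), a tortuous ICA, optional spurious bridges between nearby vessel
bends, and additive Gaussian noise. Geometry is schematic — arcs and
segments on a 128 cube at 0.6 mm isotropic spacing — because the algorithms
under test consume the skeleton graph, i.e. topology, not anatomy.

Every phantom is seed-deterministic: the same seed reproduces the volume
voxel for voxel. Each generator returns ground-truth centerlines (densely
sampled curve points rounded to the voxel grid) and per-vessel masks, so
segmentation, skeletonization, path finding, labeling, and evaluation are
all testable without any imaging data.

Variants of :func:`make_cow_phantom`:

* ``complete`` — all 14 segments; the communicating arteries close the ring.
* ``looped``   — same wiring; named for the failure substrate it provides:
  the ring through AComm gives DFS a long way around every anterior query.
* ``missing_pcomms`` — both PComms absent (the common hypoplastic variant);
  their endpoint annotations carry the ``0 0 0`` sentinel.
* ``bridged`` — a short spurious tube connects two bends of the tortuous
  R-ICA, so the globally shortest path skips the bend and is anatomically
  wrong while the ground-truth route survives as the longer detour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError
from .segmentation import BinaryMask, SeedPoint
from .volume_io import (
    CANONICAL_SEGMENTS,
    IntensityVolume,
    VesselSegmentSpec,
    write_endpoints,
    write_volume,
)

__all__ = [
    "VesselCurve",
    "PhantomSpec",
    "CowPhantom",
    "make_tube_volume",
    "make_cow_phantom",
    "write_phantom",
    "VARIANTS",
]

VARIANTS = ("complete", "looped", "missing_pcomms", "bridged")


@dataclass(frozen=True)
class VesselCurve:
    """A named tube: piecewise-linear centerline with radius and intensity."""

    name: str
    control_points: tuple[tuple[float, float, float], ...]
    radius: float = 2.0
    intensity: float = 300.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic volume; identical spec => identical volume."""

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: float = 0.6
    vessels: tuple[VesselCurve, ...] = ()
    background: float = 50.0
    noise_sd: float = 10.0
    bridges: tuple[tuple[tuple[float, float, float], tuple[float, float, float], float], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(n) != n or n < 8 for n in self.shape):
            raise InputError(f"shape must be 3 integers >= 8, got {self.shape}")
        if self.spacing <= 0:
            raise InputError(f"spacing must be positive, got {self.spacing}")
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for v in self.vessels:
            if v.radius < 1:
                raise InputError(f"vessel {v.name}: radius must be >= 1 voxel, got {v.radius}")
            if not v.intensity > self.background + 5 * self.noise_sd:
                raise InputError(
                    f"vessel {v.name}: intensity {v.intensity} must exceed background "
                    f"{self.background} + 5*noise_sd {5 * self.noise_sd} for Otsu separability"
                )
            if len(v.control_points) < 2:
                raise InputError(f"vessel {v.name}: need >= 2 control points")
            for p in v.control_points:
                if any(c < v.radius or c > n - 1 - v.radius for c, n in zip(p, self.shape)):
                    raise InputError(
                        f"vessel {v.name}: control point {p} within margin {v.radius} "
                        f"of the grid boundary {self.shape}"
                    )


def _rasterize_polyline(
    shape: tuple[int, int, int],
    points: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Voxels whose centers lie within ``radius`` of the piecewise-linear curve."""
    mask = np.zeros(shape, dtype=bool)
    r = float(radius)
    pad = int(np.ceil(r)) + 1
    for p, q in zip(points[:-1], points[1:]):
        lo = np.maximum(np.floor(np.minimum(p, q)).astype(int) - pad, 0)
        hi = np.minimum(np.ceil(np.maximum(p, q)).astype(int) + pad, np.array(shape) - 1)
        grids = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(lo, hi)), indexing="ij")
        x = np.stack([g.astype(float) for g in grids], axis=-1)
        d = q - p
        dd = float(d @ d)
        if dd == 0.0:
            closest = p
        else:
            t = np.clip(((x - p) @ d) / dd, 0.0, 1.0)
            closest = p + t[..., None] * d
        dist2 = ((x - closest) ** 2).sum(axis=-1)
        sub = mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        sub |= dist2 <= r * r
    return mask


def _centerline_voxels(points: np.ndarray, step: float = 0.25) -> list[tuple[int, int, int]]:
    """Dense samples of the curve rounded to voxels, consecutive dupes removed."""
    out: list[tuple[int, int, int]] = []
    for p, q in zip(points[:-1], points[1:]):
        seg_len = float(np.linalg.norm(q - p))
        n = max(int(np.ceil(seg_len / step)), 1)
        for t in np.linspace(0.0, 1.0, n + 1):
            vox = tuple(int(round(c)) for c in (p + t * (q - p)))
            if not out or out[-1] != vox:
                out.append(vox)
    return out


def _polyline_length_mm(points: np.ndarray, spacing: float) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum() * spacing)


def make_tube_volume(
    spec: PhantomSpec,
) -> tuple[IntensityVolume, dict[str, list[tuple[int, int, int]]], dict[str, BinaryMask]]:
    """Rasterize a :class:`PhantomSpec` into an intensity volume.

    Returns the noisy volume, per-vessel ground-truth centerline voxel
    lists, and per-vessel binary masks (noise-free geometry). Bridges are
    rasterized into the intensity image but carry no ground truth — they
    model segmentation/skeletonization artifacts, not vessels.
    """
    spec.validate()
    spacing = (spec.spacing,) * 3
    data = np.full(spec.shape, float(spec.background))
    centerlines: dict[str, list[tuple[int, int, int]]] = {}
    masks: dict[str, BinaryMask] = {}
    for v in spec.vessels:
        pts = np.asarray(v.control_points, dtype=float)
        m = _rasterize_polyline(spec.shape, pts, v.radius)
        data[m] = v.intensity
        centerlines[v.name] = _centerline_voxels(pts)
        masks[v.name] = BinaryMask(data=m, spacing=spacing)
    for a, b, r in spec.bridges:
        m = _rasterize_polyline(spec.shape, np.asarray([a, b], dtype=float), r)
        # bridges glow like vessels: they mimic noise/skeletonization artifacts
        data[m] = max((v.intensity for v in spec.vessels), default=spec.background + 100)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = IntensityVolume(data=data.astype(np.float32), spacing=spacing)
    return vol, centerlines, masks


# --- schematic circle-of-Willis geometry -------------------------------------
# Key junctions on a 128 cube (x: right->left, y: posterior->anterior,
# z: inferior->superior). The CoW ring lives in the z=64 plane; the ICAs and
# the BA rise from below.
_RICA_TERM = (44.0, 64.0, 64.0)
_LICA_TERM = (84.0, 64.0, 64.0)
_RACA_PT = (56.0, 84.0, 64.0)
_LACA_PT = (72.0, 84.0, 64.0)
_BA_TIP = (64.0, 44.0, 64.0)
_RP1_JUNC = (48.0, 40.0, 64.0)
_LP1_JUNC = (80.0, 40.0, 64.0)

# Tortuous ICA bends (an S-shaped course mimicking the carotid siphon).
_RICA_PTS = ((44.0, 64.0, 20.0), (38.0, 70.0, 30.0), (50.0, 58.0, 38.0),
             (38.0, 68.0, 48.0), _RICA_TERM)
_LICA_PTS = ((84.0, 64.0, 20.0), (90.0, 70.0, 30.0), (78.0, 58.0, 38.0),
             (90.0, 68.0, 48.0), _LICA_TERM)

_COW_CURVES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "AComm": (_RACA_PT, _LACA_PT),
    "R-A1": (_RICA_TERM, (50.0, 75.0, 64.0), _RACA_PT),
    "L-A1": (_LICA_TERM, (78.0, 75.0, 64.0), _LACA_PT),
    "R-M1": (_RICA_TERM, (33.0, 68.0, 64.0), (22.0, 72.0, 64.0)),
    "L-M1": (_LICA_TERM, (95.0, 68.0, 64.0), (106.0, 72.0, 64.0)),
    "R-ICA": _RICA_PTS,
    "L-ICA": _LICA_PTS,
    "R-PComm": (_RICA_TERM, (45.0, 52.0, 64.0), _RP1_JUNC),
    "L-PComm": (_LICA_TERM, (83.0, 52.0, 64.0), _LP1_JUNC),
    "R-P1": (_BA_TIP, _RP1_JUNC),
    "L-P1": (_BA_TIP, _LP1_JUNC),
    "R-P2": (_RP1_JUNC, (40.0, 32.0, 64.0), (34.0, 26.0, 64.0)),
    "L-P2": (_LP1_JUNC, (88.0, 32.0, 64.0), (94.0, 26.0, 64.0)),
    "BA": ((64.0, 44.0, 24.0), _BA_TIP),
}

# The spurious R-ICA bridge: a short tube between the first and third siphon
# bends, offering a shortcut that skips the middle bend.
_BRIDGE = ((38.0, 70.0, 30.0), (38.0, 68.0, 48.0), 1.5)

#: Seed clicks for the three feeding arteries, placed in low axial slices.
COW_SEEDS = (
    SeedPoint(coordinate=(44, 64, 22), label="R-ICA"),
    SeedPoint(coordinate=(84, 64, 22), label="L-ICA"),
    SeedPoint(coordinate=(64, 44, 26), label="BA"),
)


@dataclass(frozen=True)
class CowPhantom:
    """A generated CoW phantom plus every piece of ground truth about it."""

    volume: IntensityVolume
    specs: tuple[VesselSegmentSpec, ...]
    centerlines: dict[str, list[tuple[int, int, int]]]
    lengths_mm: dict[str, float]
    vessel_masks: dict[str, BinaryMask]
    seeds: tuple[SeedPoint, ...]
    variant: str
    seed: int
    phantom_spec: PhantomSpec = field(repr=False, default=None)


def make_cow_phantom(seed: int, variant: str = "complete", noise_sd: float = 10.0) -> CowPhantom:
    """Generate a CoW phantom for one of the four variants (see module docs)."""
    if variant not in VARIANTS:
        raise InputError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    omitted = {"R-PComm", "L-PComm"} if variant == "missing_pcomms" else set()
    vessels = tuple(
        VesselCurve(name=name, control_points=_COW_CURVES[name])
        for name in CANONICAL_SEGMENTS
        if name not in omitted
    )
    bridges = (_BRIDGE,) if variant == "bridged" else ()
    pspec = PhantomSpec(vessels=vessels, bridges=bridges, seed=int(seed), noise_sd=noise_sd)
    vol, centerlines, masks = make_tube_volume(pspec)

    specs = []
    for name in CANONICAL_SEGMENTS:
        if name in omitted:
            specs.append(VesselSegmentSpec(name=name, endpoint_a=(0, 0, 0), endpoint_b=(0, 0, 0)))
            continue
        pts = _COW_CURVES[name]
        a = tuple(int(round(c)) for c in pts[0])
        b = tuple(int(round(c)) for c in pts[-1])
        specs.append(VesselSegmentSpec(name=name, endpoint_a=a, endpoint_b=b))

    lengths = {
        name: _polyline_length_mm(np.asarray(_COW_CURVES[name]), pspec.spacing)
        for name in CANONICAL_SEGMENTS
        if name not in omitted
    }
    return CowPhantom(
        volume=vol,
        specs=tuple(specs),
        centerlines=centerlines,
        lengths_mm=lengths,
        vessel_masks=masks,
        seeds=COW_SEEDS,
        variant=variant,
        seed=int(seed),
        phantom_spec=pspec,
    )


def write_phantom(phantom: CowPhantom, directory: str | Path) -> dict[str, Path]:
    """Write a phantom to disk: volume, label volume, endpoints, manifest.

    The ground-truth label volume assigns each vessel its 1-based index in
    the canonical segment order (later segments overwrite at shared
    junctions, deterministically). The manifest records (seed, variant), so
    regeneration via :func:`make_cow_phantom` is bit-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": directory / "volume.nii",
        "labels": directory / "labels.nii",
        "endpoints": directory / "endpoints.txt",
        "manifest": directory / "manifest.json",
    }
    write_volume(phantom.volume, paths["volume"])
    labels = np.zeros(phantom.volume.shape, dtype=np.float32)
    for idx, name in enumerate(CANONICAL_SEGMENTS, start=1):
        if name in phantom.vessel_masks:
            labels[phantom.vessel_masks[name].data] = idx
    write_volume(IntensityVolume(data=labels, spacing=phantom.volume.spacing), paths["labels"])
    write_endpoints(list(phantom.specs), paths["endpoints"])
    manifest = {
        "seed": phantom.seed,
        "variant": phantom.variant,
        "noise_sd": phantom.phantom_spec.noise_sd,
        "shape": list(phantom.volume.shape),
        "spacing_mm": phantom.volume.spacing[0],
        "segments": {n: phantom.lengths_mm.get(n) for n in CANONICAL_SEGMENTS},
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return paths


def load_phantom_manifest(path: str | Path) -> CowPhantom:
    """Regenerate the exact phantom recorded in a manifest file."""
    with open(path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    return make_cow_phantom(
        seed=manifest["seed"], variant=manifest["variant"], noise_sd=manifest["noise_sd"]
    )
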