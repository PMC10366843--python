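"""NIfTI volume I/O, isotropic resampling, and endpoint-annotation parsing.

The coordinate convention used throughout the package is 0-based integer
voxel indices in ``(x, y, z)`` axis order matching the NIfTI array layout.
Annotated endpoint coordinates are interpreted on the resampled (isotropic)
grid, because annotation happens on the skeleton of the interpolated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InputError, ParseError

__all__ = [
    "CANONICAL_SEGMENTS",
    "SENTINEL",
    "IntensityVolume",
    "VesselSegmentSpec",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "parse_endpoints",
    "write_endpoints",
]

#: The 14 canonical circle-of-Willis segment names, in canonical file order.
CANONICAL_SEGMENTS: tuple[str, ...] = (
    "AComm",
    "R-A1",
    "L-A1",
    "R-M1",
    "L-M1",
    "R-ICA",
    "L-ICA",
    "R-PComm",
    "L-PComm",
    "R-P1",
    "L-P1",
    "R-P2",
    "L-P2",
    "BA",
)

#: Sentinel coordinate recorded for a vessel segment with no visible centerline.
SENTINEL: tuple[int, int, int] = (0, 0, 0)


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar image with per-axis physical voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise InputError(f"expected 3D volume, got {data.ndim}D data")
        if any(s < 1 for s in data.shape):
            raise InputError(f"every axis must have length >= 1, got shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise InputError(f"spacing must have 3 entries, got {len(spacing)}")
        if not all(np.isfinite(s) and s > 0 for s in spacing):
            raise InputError(f"spacing must be strictly positive and finite, got {spacing}")
        if not np.all(np.isfinite(data)):
            raise InputError("data contains non-finite intensities")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class VesselSegmentSpec:
    """A named vessel segment with its two annotated endpoint voxels.

    ``missing`` is true iff both endpoints carry the ``0 0 0`` sentinel,
    meaning the annotator found no centerline for this segment.
    """

    name: str
    endpoint_a: tuple[int, int, int]
    endpoint_b: tuple[int, int, int]

    def __post_init__(self):
        if self.name not in CANONICAL_SEGMENTS:
            raise InputError(f"unknown segment name {self.name!r}")
        a = tuple(int(c) for c in self.endpoint_a)
        b = tuple(int(c) for c in self.endpoint_b)
        if len(a) != 3 or len(b) != 3:
            raise InputError("endpoints must be 3D voxel coordinates")
        if (a == SENTINEL) != (b == SENTINEL):
            raise InputError(
                f"segment {self.name}: the 0 0 0 sentinel must apply to both endpoints"
            )
        if a != SENTINEL and a == b:
            raise InputError(f"segment {self.name}: endpoints must differ")
        object.__setattr__(self, "endpoint_a", a)
        object.__setattr__(self, "endpoint_b", b)

    @property
    def missing(self) -> bool:
        return self.endpoint_a == SENTINEL and self.endpoint_b == SENTINEL


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a NIfTI-1 file as an :class:`IntensityVolume`.

    Spacing is taken from the header zooms (pixdim). Raises
    :class:`~cowlabel.errors.InputError` for non-3D images or non-positive
    spacing.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise InputError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise InputError(f"expected 3D volume in {path}, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    return IntensityVolume(data=np.asarray(data, dtype=np.float32), spacing=tuple(zooms))


def write_volume(vol: IntensityVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float32) with a diagonal spacing affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _axis_coords(n_in: int, s_in: float, s_out: float) -> np.ndarray:
    """Output sample positions along one axis, in input index units.

    The output grid spans the same physical extent as the input:
    ``n_out = round((n_in - 1) * s_in / s_out) + 1`` samples at physical
    positions ``k * s_out``, clamped to the input range at the edges.
    """
    n_out = int(round((n_in - 1) * s_in / s_out)) + 1
    pos_mm = np.arange(n_out) * s_out
    return np.clip(pos_mm / s_in, 0.0, n_in - 1)


def _cubic_interp_axis(arr: np.ndarray, coords: np.ndarray, axis: int) -> np.ndarray:
    """Catmull-Rom cubic-convolution interpolation along one axis.

    Sample positions are in input index units; edge handling clamps
    neighbor indices (edge-value replication).
    """
    n = arr.shape[axis]
    base = np.floor(coords).astype(int)
    base = np.clip(base, 0, n - 1)
    t = coords - base
    # Keys kernel, a = -0.5 (Catmull-Rom): exact on linear and quadratic data
    w = (
        -0.5 * t**3 + t**2 - 0.5 * t,
        1.5 * t**3 - 2.5 * t**2 + 1.0,
        -1.5 * t**3 + 2.0 * t**2 + 0.5 * t,
        0.5 * t**3 - 0.5 * t**2,
    )
    out = np.zeros(arr.shape[:axis] + (len(coords),) + arr.shape[axis + 1 :], dtype=np.float64)
    shape = [1] * out.ndim
    shape[axis] = len(coords)
    for k, wk in enumerate(w, start=-1):
        idx = np.clip(base + k, 0, n - 1)
        out += np.take(arr, idx, axis=axis) * wk.reshape(shape)
    return out


def resample_isotropic(vol: IntensityVolume, target_spacing: float) -> IntensityVolume:
    """Resample a volume to isotropic spacing with cubic interpolation.

    Interpolation is separable cubic convolution (Catmull-Rom); axes
    already at the target spacing pass through unchanged. A target more
    than 10x coarser than any axis spacing triggers a warning (severe
    downsampling without anti-aliasing), not an error.
    """
    t = float(target_spacing)
    if not np.isfinite(t) or t <= 0:
        raise InputError(f"target_spacing must be positive, got {target_spacing}")
    if all(abs(s - t) < 1e-9 for s in vol.spacing):
        return vol
    if any(t > 10 * s for s in vol.spacing):
        warnings.warn(
            f"target spacing {t} mm is >10x coarser than input spacing {vol.spacing}",
            stacklevel=2,
        )
    out = np.asarray(vol.data, dtype=np.float64)
    for axis, (n_in, s_in) in enumerate(zip(vol.shape, vol.spacing)):
        if abs(s_in - t) < 1e-9:
            continue
        out = _cubic_interp_axis(out, _axis_coords(n_in, s_in, t), axis)
    return IntensityVolume(data=out.astype(vol.data.dtype, copy=False), spacing=(t, t, t))


def parse_endpoints(path: str | Path) -> list[VesselSegmentSpec]:
    """Parse an endpoint-annotation text file into 14 segment specs.

    Dialect: one segment per line, ``NAME x1 y1 z1 x2 y2 z2``,
    whitespace-separated; ``#`` starts a comment; blank lines ignored.
    The sentinel is all six coordinates zero. Exactly one line per
    canonical segment name is required.
    """
    specs: dict[str, VesselSegmentSpec] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 7:
                raise ParseError(
                    f"expected 'NAME x1 y1 z1 x2 y2 z2' (7 tokens), got {len(tokens)}",
                    line=lineno,
                )
            name = tokens[0]
            if name not in CANONICAL_SEGMENTS:
                raise ParseError(f"unknown segment name {name!r}", line=lineno)
            if name in specs:
                raise ParseError(f"duplicate segment {name!r}", line=lineno)
            try:
                coords = [int(tok) for tok in tokens[1:]]
            except ValueError:
                raise ParseError(f"non-integer coordinate in {line!r}", line=lineno) from None
            try:
                specs[name] = VesselSegmentSpec(
                    name=name,
                    endpoint_a=tuple(coords[:3]),
                    endpoint_b=tuple(coords[3:]),
                )
            except InputError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    absent = [name for name in CANONICAL_SEGMENTS if name not in specs]
    if absent:
        raise ParseError(f"missing segments: {', '.join(absent)}")
    return [specs[name] for name in CANONICAL_SEGMENTS]


def write_endpoints(specs: list[VesselSegmentSpec], path: str | Path) -> None:
    """Write segment specs in canonical order in the annotation dialect."""
    by_name = {s.name: s for s in specs}
    absent = [name for name in CANONICAL_SEGMENTS if name not in by_name]
    if absent:
        raise InputError(f"missing segments: {', '.join(absent)}")
    if len(specs) != len(by_name):
        raise InputError("duplicate segments in spec list")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# segment x1 y1 z1 x2 y2 z2  (0 0 0 0 0 0 = undetected)\n")
        for name in CANONICAL_SEGMENTS:
            s = by_name[name]
            fh.write(f"{name} {' '.join(map(str, s.endpoint_a + s.endpoint_b))}\n")
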