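"""Binary lesion (VOI) drawing operators and persistence.

Drawing happens in image space, slice by slice, the way lesions are traced
on the acquired grid to avoid interpolation aliasing.  A :class:`VOI`
shares its reference volume's grid; ``.voi`` files are ordinary gzipped
uint8 NIfTI-1 volumes, so renaming one to ``.nii.gz`` makes it readable by
any NIfTI tool.

The legacy run-length ROI codec stores each slice as 16-bit
(start_offset, length) runs over the row-major in-plane pixel order, which
caps the supported slice size at 65536 in-plane pixels.  The byte layout
here (magic ``MRO1``) is a documented dialect that reproduces that
capacity; bit-compatibility with historical files is not claimed.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import CapacityError, CorruptFileError, ValidationError
from .volio import Volume, read_volume, volume_from_array, write_nifti

log = logging.getLogger(__name__)

RLE_MAX_PIXELS = 65536  # 16-bit offset/length fields


@dataclass
class VOI:
    """A binary volume of interest on a reference grid."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValidationError(f"VOI mask must be 3D, got ndim={self.mask.ndim}")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("VOI mask values must be 0/1")
        self.mask = self.mask.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("VOI affine must be 4x4")

    @classmethod
    def empty(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "VOI":
        return cls(mask=np.zeros(shape, dtype=np.uint8), affine=affine)

    @classmethod
    def on_grid(cls, vol: Volume, mask: np.ndarray | None = None) -> "VOI":
        if mask is None:
            mask = np.zeros(vol.shape, dtype=np.uint8)
        return cls(mask=mask, affine=vol.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    def copy(self) -> "VOI":
        return VOI(mask=self.mask.copy(), affine=self.affine.copy())

    def to_volume(self) -> Volume:
        return volume_from_array(self.mask, affine=self.affine, datatype="uint8",
                                 source_format="voi")


@dataclass
class LegacyRoiSlice:
    """One slice of a VOI as sorted, non-overlapping 16-bit runs."""

    slice_index: int
    runs: list[tuple[int, int]] = field(default_factory=list)


def _plane(voi: VOI, slice_index: int, axis: int) -> np.ndarray:
    if not 0 <= axis <= 2:
        raise ValidationError(f"axis must be 0, 1 or 2, got {axis}")
    n = voi.shape[axis]
    if not 0 <= slice_index < n:
        raise ValidationError(
            f"slice {slice_index} out of range [0, {n - 1}] along axis {axis}")
    return np.take(voi.mask, slice_index, axis=axis)


def _put_plane(voi: VOI, slice_index: int, axis: int, plane: np.ndarray) -> VOI:
    out = voi.copy()
    sl: list = [slice(None)] * 3
    sl[axis] = slice_index
    out.mask[tuple(sl)] = plane.astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# drawing operators (each returns a new VOI; only the addressed slice changes)

def pen_stroke(voi: VOI, slice_index: int, polyline, thickness: float = 1.0,
               erase: bool = False, axis: int = 2) -> VOI:
    """Paint (or erase) a polyline with a round brush of the given thickness.

    In-plane voxels whose center lies within ``thickness / 2`` (Euclidean)
    of any segment are affected.  A single point is a degenerate segment.
    """
    if thickness < 1:
        raise ValidationError(f"thickness must be >= 1 voxel, got {thickness}")
    pts = np.atleast_2d(np.asarray(polyline, dtype=float))
    if pts.shape[1] != 2:
        raise ValidationError("polyline must be a list of 2D in-plane points")
    plane = _plane(voi, slice_index, axis).copy()
    h, w = plane.shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    grid = np.stack([yy, xx], axis=-1).astype(float)
    hit = np.zeros((h, w), dtype=bool)
    segs = [(pts[0], pts[0])] if len(pts) == 1 else list(zip(pts[:-1], pts[1:]))
    r = thickness / 2.0
    for a, b in segs:
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d2 = ((grid - a) ** 2).sum(axis=-1)
        else:
            t = np.clip(((grid - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d2 = ((grid - proj) ** 2).sum(axis=-1)
        hit |= d2 <= r * r + 1e-12
    plane[hit] = 0 if erase else 1
    return _put_plane(voi, slice_index, axis, plane)


def draw_ellipse(voi: VOI, slice_index: int, bounding_box, filled: bool = True,
                 erase: bool = False, axis: int = 2) -> VOI:
    """Draw the ellipse inscribed in ``bounding_box`` = ((r0, c0), (r1, c1)).

    ``filled`` paints the interior; otherwise only the one-voxel-thick
    boundary (filled minus its 4-connected erosion).
    """
    (r0, c0), (r1, c1) = bounding_box
    r0, r1 = sorted((float(r0), float(r1)))
    c0, c1 = sorted((float(c0), float(c1)))
    if r1 - r0 <= 0 or c1 - c0 <= 0:
        raise ValidationError(f"degenerate bounding box {bounding_box}")
    plane = _plane(voi, slice_index, axis).copy()
    h, w = plane.shape
    cy, cx = (r0 + r1) / 2.0, (c0 + c1) / 2.0
    ry, rx = (r1 - r0) / 2.0, (c1 - c0) / 2.0
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0 + 1e-12
    if not filled:
        inside = inside & ~ndimage.binary_erosion(
            inside, structure=ndimage.generate_binary_structure(2, 1))
    plane[inside] = 0 if erase else 1
    return _put_plane(voi, slice_index, axis, plane)


def bucket_fill(voi: VOI, slice_index: int, seed_point, axis: int = 2) -> VOI:
    """4-connected flood fill of the empty region containing ``seed_point``.

    Filling stops at set voxels and at the slice border.  A seed on an
    already-set voxel is a no-op (logged).
    """
    plane = _plane(voi, slice_index, axis).copy()
    r, c = int(seed_point[0]), int(seed_point[1])
    h, w = plane.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValidationError(f"seed {seed_point} outside the {h}x{w} slice")
    if plane[r, c]:
        log.info("bucket fill seed (%d, %d) already set; no-op", r, c)
        return voi.copy()
    labels, _ = ndimage.label(plane == 0,
                              structure=ndimage.generate_binary_structure(2, 1))
    plane[labels == labels[r, c]] = 1
    return _put_plane(voi, slice_index, axis, plane)


def intensity_grow(source: Volume, seed_voxel, low: float, high: float,
                   connectivity: int = 6) -> VOI:
    """3D region growing: the connected component of [low, high] voxels at seed."""
    if connectivity not in (6, 26):
        raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")
    i, j, k = (int(x) for x in seed_voxel)
    seed_val = float(source.data[i, j, k])
    if not low <= seed_val <= high:
        raise ValidationError(
            f"seed intensity {seed_val} outside [{low}, {high}]")
    within = (source.data >= low) & (source.data <= high)
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, _ = ndimage.label(within, structure=structure)
    mask = (labels == labels[i, j, k]).astype(np.uint8)
    return VOI(mask=mask, affine=source.affine)


_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _ball(radius: int) -> np.ndarray:
    if radius not in _SPHERE_CACHE:
        r = int(radius)
        ax = np.arange(-r, r + 1)
        ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
        _SPHERE_CACHE[radius] = (ii ** 2 + jj ** 2 + kk ** 2) <= r ** 2
    return _SPHERE_CACHE[radius]


def morph(voi: VOI, operation: str, radius_voxels: int = 1) -> VOI:
    """Binary morphology with a discrete spherical structuring element."""
    if radius_voxels < 1:
        raise ValidationError(f"radius must be >= 1, got {radius_voxels}")
    ball = _ball(int(radius_voxels))
    m = voi.mask.astype(bool)
    if operation == "dilate":
        out = ndimage.binary_dilation(m, structure=ball)
    elif operation == "erode":
        out = ndimage.binary_erosion(m, structure=ball)
    elif operation == "open":
        out = ndimage.binary_opening(m, structure=ball)
    elif operation == "close":
        out = ndimage.binary_closing(m, structure=ball)
    else:
        raise ValidationError(
            f"operation must be dilate/erode/open/close, got {operation!r}")
    return VOI(mask=out.astype(np.uint8), affine=voi.affine)


def copy_slice(voi: VOI, from_index: int, axis: int = 2) -> np.ndarray:
    """Copy one slice's mask into an independent buffer."""
    return _plane(voi, from_index, axis).copy()


def paste_slice(voi: VOI, to_index: int, buffer: np.ndarray, axis: int = 2) -> VOI:
    """Replace the target slice with a previously copied buffer."""
    plane = _plane(voi, to_index, axis)
    buffer = np.asarray(buffer)
    if buffer.shape != plane.shape:
        raise ValidationError(
            f"buffer shape {buffer.shape} != slice shape {plane.shape}")
    return _put_plane(voi, to_index, axis, buffer)


# ---------------------------------------------------------------------------
# persistence

def save_voi(voi: VOI, path: str | Path) -> Path:
    """Save as gzipped uint8 NIfTI-1 (`.voi`; rename to `.nii.gz` for other tools)."""
    return write_nifti(voi.to_volume(), path, gzipped=True)


def load_voi(path: str | Path) -> VOI:
    vol = read_volume(path)
    return VOI(mask=(np.asarray(vol.data) != 0).astype(np.uint8), affine=vol.affine)


# ---------------------------------------------------------------------------
# legacy run-length codec

def rle_encode_slice(plane: np.ndarray, slice_index: int = 0) -> LegacyRoiSlice:
    """Encode one binary plane as row-major 16-bit (start, length) runs.

    Planes larger than 65536 in-plane pixels cannot be addressed by the
    16-bit fields and are refused.  Runs longer than 65535 are split into
    adjacent runs so every stored field fits in 16 bits.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValidationError(f"plane must be 2D, got ndim={plane.ndim}")
    if plane.size > RLE_MAX_PIXELS:
        raise CapacityError(
            f"plane has {plane.size} in-plane pixels; the legacy RLE format "
            f"is limited to a maximum of {RLE_MAX_PIXELS} pixels in-plane")
    flat = (plane.ravel(order="C") != 0).astype(np.int8)
    edges = np.diff(np.concatenate([[0], flat, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    runs: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        length = int(e - s)
        start = int(s)
        while length > 0xFFFF:
            runs.append((start, 0xFFFF))
            start += 0xFFFF
            length -= 0xFFFF
        runs.append((start, length))
    return LegacyRoiSlice(slice_index=int(slice_index), runs=runs)


def rle_decode_slice(rle: LegacyRoiSlice, shape: tuple[int, int]) -> np.ndarray:
    """Reconstruct the binary plane from its runs."""
    n = int(shape[0]) * int(shape[1])
    if n > RLE_MAX_PIXELS:
        raise CapacityError(
            f"plane has {n} in-plane pixels; the legacy RLE format is limited "
            f"to a maximum of {RLE_MAX_PIXELS} pixels in-plane")
    flat = np.zeros(n, dtype=np.uint8)
    for start, length in rle.runs:
        if start < 0 or length < 0 or start + length > n:
            raise CorruptFileError(
                f"run ({start}, {length}) exceeds the {n}-pixel plane")
        flat[start:start + length] = 1
    return flat.reshape(shape, order="C")


_ROI_MAGIC = b"MRO1"


def save_roi(voi: VOI, path: str | Path, axis: int = 2) -> Path:
    """Write the legacy RLE ROI dialect (little-endian, 16-bit fields)."""
    path = Path(path)
    planes = [np.take(voi.mask, k, axis=axis) for k in range(voi.shape[axis])]
    h, w = planes[0].shape
    if h * w > RLE_MAX_PIXELS:
        raise CapacityError(
            f"{h}x{w} slices exceed the {RLE_MAX_PIXELS}-pixel in-plane limit")
    encoded = [rle_encode_slice(p, k) for k, p in enumerate(planes) if p.any()]
    buf = bytearray(_ROI_MAGIC)
    buf += struct.pack("<HHH", h, w, len(encoded))
    for rle in encoded:
        buf += struct.pack("<HH", rle.slice_index, len(rle.runs))
        for start, length in rle.runs:
            buf += struct.pack("<HH", start, length & 0xFFFF)
    path.write_bytes(bytes(buf))
    return path


def load_roi(path: str | Path, n_slices: int | None = None,
             affine: np.ndarray | None = None, axis: int = 2) -> VOI:
    """Read the legacy RLE ROI dialect back into a VOI.

    ``n_slices`` defaults to one past the largest stored slice index; the
    affine defaults to identity (the legacy format carries no geometry).
    """
    raw = Path(path).read_bytes()
    if raw[:4] != _ROI_MAGIC:
        raise CorruptFileError(f"{path} is not a legacy ROI file (bad magic)")
    h, w, n_stored = struct.unpack_from("<HHH", raw, 4)
    pos = 10
    slices: list[LegacyRoiSlice] = []
    for _ in range(n_stored):
        idx, n_runs = struct.unpack_from("<HH", raw, pos)
        pos += 4
        runs = []
        for _ in range(n_runs):
            start, length = struct.unpack_from("<HH", raw, pos)
            pos += 4
            runs.append((start, length if length else 0x10000))
        slices.append(LegacyRoiSlice(slice_index=idx, runs=runs))
    if n_slices is None:
        n_slices = max((s.slice_index for s in slices), default=-1) + 1 or 1
    shape3 = [h, w]
    shape3.insert(axis, n_slices)
    mask = np.zeros(shape3, dtype=np.uint8)
    for s in slices:
        sl: list = [slice(None)] * 3
        sl[axis] = s.slice_index
        mask[tuple(sl)] = rle_decode_slice(s, (h, w))
    return VOI(mask=mask, affine=np.eye(4) if affine is None else affine)
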