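"""Voxel <-> world geometry, canonical reorientation and reslicing.

Conventions used throughout voxview:

* voxel indices are 0-based and address voxel *centers*;
* world space is RAS+ millimetres;
* nearest-neighbour rounding is round-half-away-from-zero;
* samples outside the grid are background-filled with 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .volio import Volume, volume_from_array


@dataclass(frozen=True)
class GridSpec:
    """A target sampling grid: shape plus voxel->world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValidationError("grid affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValidationError("grid affine is singular")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def of(cls, vol: Volume) -> "GridSpec":
        return cls(shape=vol.shape, affine=vol.affine)


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, ties away from zero (the package-wide rule)."""
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x))


def voxel_to_world(vol: Volume | GridSpec, ijk) -> np.ndarray:
    """Map (continuous) voxel indices to world mm.  Accepts (3,) or (N, 3)."""
    aff = vol.affine
    pts = np.asarray(ijk, dtype=float)
    return pts @ aff[:3, :3].T + aff[:3, 3]


def world_to_voxel(vol: Volume | GridSpec, xyz) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`."""
    aff = np.asarray(vol.affine, dtype=float)
    if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise ValidationError("affine is singular; world_to_voxel undefined")
    inv = np.linalg.inv(aff)
    pts = np.asarray(xyz, dtype=float)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def _sample_array(data: np.ndarray, coords: np.ndarray, interp: str) -> np.ndarray:
    """coords: (3, N) continuous voxel coordinates -> (N,) intensities."""
    if interp == "trilinear":
        return map_coordinates(np.asarray(data, dtype=np.float64), coords,
                               order=1, mode="constant", cval=0.0)
    if interp == "nearest":
        idx = round_half_away(coords).astype(np.int64)
        shape = np.asarray(data.shape).reshape(3, 1)
        valid = np.all((idx >= 0) & (idx < shape), axis=0)
        out = np.zeros(coords.shape[1], dtype=np.float64)
        if valid.any():
            out[valid] = np.asarray(data, dtype=np.float64)[
                idx[0, valid], idx[1, valid], idx[2, valid]]
        return out
    raise ValidationError(f"interp must be 'nearest' or 'trilinear', got {interp!r}")


def sample(vol: Volume | np.ndarray, ijk, interp: str = "trilinear"):
    """Sample a volume at continuous voxel coordinates.

    ``ijk`` may be a single (i, j, k) triple or an (N, 3) array.  Nearest
    uses round-half-away-from-zero; trilinear averages the 8 surrounding
    grid values.  Coordinates outside the grid return 0 (background fill).
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    pts = np.asarray(ijk, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = _sample_array(data, pts.T, interp)
    return float(out[0]) if single else out


def canonical_ras(vol: Volume) -> Volume:
    """Reorder/flip axes (losslessly) so the affine is maximally diagonal RAS+.

    No interpolation: the multiset of intensities is preserved and every
    voxel keeps its world position.  Idempotent.
    """
    aff = vol.affine
    R = aff[:3, :3]
    # assign each voxel axis to the world axis it most influences
    world_ax, vox_ax = linear_sum_assignment(-np.abs(R))
    perm = np.empty(3, dtype=int)
    for w, j in zip(world_ax, vox_ax):
        perm[w] = j
    flips = np.array([R[w, perm[w]] < 0 for w in range(3)])

    data = np.transpose(vol.data, axes=tuple(perm))
    M = np.zeros((4, 4))
    M[3, 3] = 1.0
    for w in range(3):
        j = perm[w]
        if flips[w]:
            M[j, w] = -1.0
            M[j, 3] = vol.shape[j] - 1
            data = np.flip(data, axis=w)
        else:
            M[j, w] = 1.0
    new_aff = aff @ M
    vs = tuple(float(vol.header.voxel_size[perm[w]]) for w in range(3))
    return volume_from_array(np.ascontiguousarray(data), affine=new_aff,
                             voxel_size=vs, datatype=vol.header.datatype,
                             description=vol.header.description,
                             source_format=vol.source_format)


def reslice_world(vol: Volume, target: GridSpec, interp: str = "trilinear") -> Volume:
    """Resample ``vol`` onto ``target``'s grid through world space."""
    M = np.linalg.inv(vol.affine) @ target.affine  # target index -> source index
    nx, ny, nz = target.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    idx = np.stack([ii, jj, kk], axis=0).reshape(3, -1).astype(float)
    src = M[:3, :3] @ idx + M[:3, 3:4]
    vals = _sample_array(vol.data, src, interp)
    out = vals.reshape(target.shape)
    if interp == "nearest" and not np.issubdtype(vol.data.dtype, np.floating):
        out = out.astype(vol.data.dtype)
    return volume_from_array(out, affine=target.affine,
                             datatype=vol.header.datatype,
                             source_format=vol.source_format)


def isotropic_grid(vol: Volume, spacing: float | None = None) -> GridSpec:
    """World-space display grid: isotropic, RAS-axis-aligned, covering ``vol``.

    Spacing defaults to the smallest source voxel dimension.
    """
    if spacing is None:
        spacing = float(min(vol.header.voxel_size))
    if spacing <= 0:
        raise ValidationError("grid spacing must be positive")
    shape = np.asarray(vol.shape)
    corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                        for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)],
                       dtype=float)
    world = voxel_to_world(vol, corners)
    lo, hi = world.min(axis=0), world.max(axis=0)
    n = np.maximum(1, np.floor((hi - lo) / spacing + 0.5).astype(int) + 1)
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = lo
    return GridSpec(shape=tuple(int(x) for x in n), affine=aff)
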