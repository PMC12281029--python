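"""Seeded phantom volumes and lesion sets.

Every other module is testable without downloads: a :class:`PhantomSpec`
describes geometric primitives painted onto a grid (later primitives
overwrite earlier ones), optionally followed by Gaussian noise, and
``write_fixture_suite`` serializes one identical phantom in every format
the I/O layer supports.

Randomness uses NumPy's default PCG64 generator seeded from the spec, so
identical spec + seed reproduces bit-identical voxel data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .voi_draw import VOI
from .volio import Volume, read_volume, volume_from_array, write_volume

_PRIMITIVE_KINDS = ("sphere", "box", "linear_gradient")


@dataclass(frozen=True)
class Primitive:
    """One painted shape: a sphere, an axis-aligned box, or an intensity ramp."""

    kind: str
    center: tuple[float, float, float] | None = None
    radius: float | None = None          # sphere
    size: tuple[float, float, float] | None = None  # box full extents
    axis: int = 0                        # linear_gradient direction
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _PRIMITIVE_KINDS:
            raise ValidationError(
                f"primitive kind must be one of {_PRIMITIVE_KINDS}, got {self.kind!r}")
        if self.kind == "sphere" and (self.center is None or self.radius is None
                                      or self.radius <= 0):
            raise ValidationError("sphere needs a center and a positive radius")
        if self.kind == "box" and (self.center is None or self.size is None
                                   or any(s <= 0 for s in self.size)):
            raise ValidationError("box needs a center and positive extents")
        if self.kind == "linear_gradient" and self.axis not in (0, 1, 2):
            raise ValidationError("gradient axis must be 0, 1 or 2")


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic description of a synthetic test volume."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    primitives: tuple[Primitive, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValidationError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(
                f"voxel_size must be 3 positive reals, got {self.voxel_size}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        object.__setattr__(self, "primitives", tuple(self.primitives))


def default_brain_like_spec(seed: int = 0) -> PhantomSpec:
    """A small head-phantom-like default: bright shell, inner structure, ramp."""
    return PhantomSpec(
        shape=(32, 32, 24),
        voxel_size=(1.0, 1.0, 1.5),
        primitives=(
            Primitive("sphere", center=(15.5, 15.5, 11.5), radius=13, intensity=60.0),
            Primitive("sphere", center=(15.5, 15.5, 11.5), radius=11, intensity=100.0),
            Primitive("box", center=(10.0, 20.0, 12.0), size=(6.0, 6.0, 6.0),
                      intensity=160.0),
            Primitive("sphere", center=(21.0, 10.0, 10.0), radius=3, intensity=220.0),
        ),
        noise_sigma=2.0,
        seed=seed,
    )


def make_phantom(spec: PhantomSpec) -> Volume:
    """Render a spec to a float32 Volume with a diag(voxel_size) affine."""
    data = np.zeros(spec.shape, dtype=np.float64)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in spec.shape), indexing="ij")
    for prim in spec.primitives:
        if prim.kind == "sphere":
            cx, cy, cz = prim.center  # type: ignore[misc]
            d2 = (ii - cx) ** 2 + (jj - cy) ** 2 + (kk - cz) ** 2
            data[d2 <= prim.radius ** 2] = prim.intensity  # voxel-center, inclusive
        elif prim.kind == "box":
            cx, cy, cz = prim.center  # type: ignore[misc]
            sx, sy, sz = prim.size  # type: ignore[misc]
            inside = ((np.abs(ii - cx) <= sx / 2) & (np.abs(jj - cy) <= sy / 2)
                      & (np.abs(kk - cz) <= sz / 2))
            data[inside] = prim.intensity
        else:  # linear_gradient: 0 .. intensity along the chosen axis
            n = spec.shape[prim.axis]
            coord = (ii, jj, kk)[prim.axis]
            ramp = coord / (n - 1) if n > 1 else np.zeros_like(coord, dtype=float)
            data[...] = ramp * prim.intensity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return volume_from_array(data.astype(np.float32),
                             voxel_size=spec.voxel_size, datatype="float32",
                             description=f"voxview phantom seed={spec.seed}")


def make_lesion_set(n: int, grid: Volume, seed: int = 0,
                    radius_range: tuple[float, float] = (2.0, 5.0)) -> list[VOI]:
    """n random spherical lesions on ``grid``'s geometry, reproducible from seed."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    r_lo, r_hi = radius_range
    if not 0 < r_lo <= r_hi:
        raise ValidationError(f"bad radius_range {radius_range}")
    shape = np.asarray(grid.shape, dtype=float)
    if np.any(2 * r_hi + 1 > shape):
        raise ValidationError(
            f"radius {r_hi} does not fit inside grid of shape {grid.shape}")
    rng = np.random.default_rng(seed)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid.shape), indexing="ij")
    vois = []
    for _ in range(n):
        radius = rng.uniform(r_lo, r_hi)
        center = np.array([rng.uniform(radius, dim - 1 - radius) for dim in shape])
        d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
        vois.append(VOI(mask=(d2 <= radius ** 2).astype(np.uint8),
                        affine=grid.affine))
    return vois


#: (file name suffix, format id) for one full fixture suite
SUITE_FORMATS: tuple[tuple[str, str], ...] = (
    ("phantom.nii", "nifti1"),
    ("phantom.nii.gz", "nifti1_gz"),
    ("phantom.mgh", "mgh"),
    ("phantom.mgz", "mgz"),
    ("phantom+orig.HEAD", "afni"),
    ("phantom.nrrd", "nrrd"),
    ("phantom.vtk", "vtk_legacy"),
)


def write_fixture_suite(directory: str | Path,
                        spec: PhantomSpec | None = None) -> list[dict[str, str]]:
    """Serialize one phantom in all 7 supported formats.

    Returns the manifest (also written as ``manifest.jsonl``): one
    ``{"path", "format"}`` record per file.  Every file re-reads to a
    voxel-identical array on an equivalent affine.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = default_brain_like_spec()
    vol = make_phantom(spec)
    manifest: list[dict[str, str]] = []
    for fname, fmt in SUITE_FORMATS:
        path = write_volume(vol, directory / fname, fmt)
        manifest.append({"path": str(path), "format": fmt})
    with open(directory / "manifest.jsonl", "w") as fh:
        for record in manifest:
            fh.write(json.dumps(record) + "\n")
    return manifest


def read_manifest(directory: str | Path) -> list[dict[str, str]]:
    with open(Path(directory) / "manifest.jsonl") as fh:
        return [json.loads(line) for line in fh if line.strip()]
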