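"""Slice extraction and mosaic composition, exported as PNG.

Axial, coronal and sagittal planes are defined on the canonical RAS+
volume (axes 2, 1 and 0).  Image-space display indexes the raw grid with
square screen pixels per voxel (anisotropy remains visible); world-space
display reslices the whole scene onto an isotropic grid whose spacing is
the smallest source voxel dimension before slicing.

Mosaics lay arbitrary (not necessarily equidistant) slice lists out in
row-major order; a nonzero overlap fraction slides adjacent tiles into
each other horizontally, later slices painting over earlier ones with
zero-intensity background treated as transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ValidationError
from .layers import Scene, WindowedLayer, blend_layers, layer_rgba
from .spatial import canonical_ras, isotropic_grid, reslice_world, round_half_away, world_to_voxel

AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class MosaicSpec:
    """Declarative description of a slice montage."""

    axis: str = "axial"
    slices: list[float] = field(default_factory=list)
    columns: int = 4
    overlap_fraction: float = 0.0
    space: str = "image"
    crosshair: tuple[float, float, float] | None = None
    scale: int = 1

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValidationError(f"axis must be one of {sorted(AXES)}, got {self.axis!r}")
        if not self.slices:
            raise ValidationError("slice list must be nonempty")
        if not 0.0 <= self.overlap_fraction <= 0.9:
            raise ValidationError(
                f"overlap_fraction must be in [0, 0.9], got {self.overlap_fraction}")
        if self.columns < 1:
            raise ValidationError(f"columns must be >= 1, got {self.columns}")
        if self.space not in ("image", "world"):
            raise ValidationError(f"space must be image or world, got {self.space!r}")
        if self.scale < 1:
            raise ValidationError(f"scale must be a positive integer, got {self.scale}")


def _canonical_scene(scene: Scene, space: str) -> Scene:
    """Reorient (image space) or reslice (world space) every layer onto one grid."""
    base_vol = canonical_ras(scene.base.volume)
    if space == "world":
        grid = isotropic_grid(base_vol)
        base_vol = reslice_world(base_vol, grid, interp="trilinear")
        overlays = []
        for ov in scene.overlays:
            ov_vol = reslice_world(canonical_ras(ov.volume), grid, interp="trilinear")
            overlays.append(WindowedLayer(ov_vol, ov.display_min, ov.display_max,
                                          ov.lut, ov.opacity))
    else:
        overlays = []
        for ov in scene.overlays:
            ov_vol = canonical_ras(ov.volume)
            if ov_vol.shape != base_vol.shape:
                raise ValidationError(
                    f"image-space overlay shape {ov_vol.shape} != base {base_vol.shape}; "
                    "reslice explicitly for world-space display")
            overlays.append(WindowedLayer(ov_vol, ov.display_min, ov.display_max,
                                          ov.lut, ov.opacity))
    base = WindowedLayer(base_vol, scene.base.display_min, scene.base.display_max,
                         scene.base.lut, scene.base.opacity)
    return Scene(base=base, overlays=overlays)


def render_plane(scene: Scene, axis: int, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Window/colorize/blend one raw-orientation plane.

    Returns (RGB uint8 plane, foreground mask).  ``scene`` must already be
    on a single grid (see :func:`_canonical_scene`).
    """
    n = scene.base.volume.shape[axis]
    if not 0 <= index < n:
        raise ValidationError(f"slice {index} out of range [0, {n - 1}]")
    base_vals = np.take(scene.base.volume.data, index, axis=axis)
    base_rgba = layer_rgba(scene.base, base_vals)
    fg = base_vals != 0
    overlays = []
    for ov in scene.overlays:
        vals = np.take(ov.volume.data, index, axis=axis)
        rgba = layer_rgba(ov, vals, transparent_below_min=True)
        overlays.append((rgba, ov.opacity))
        fg = fg | ((rgba[..., 3] > 0) & (ov.opacity > 0))
    rgb = blend_layers(base_rgba[..., :3], overlays)
    return rgb, fg


def _display_transform(plane: np.ndarray) -> np.ndarray:
    # raw (row, col) axes -> screen: second in-plane axis points up
    return np.flipud(np.swapaxes(plane, 0, 1))


def _resolve_index(scene: Scene, axis: int, position: float, space: str) -> int:
    vol = scene.base.volume
    if space == "world":
        center = (np.asarray(vol.shape, dtype=float) - 1) / 2.0
        probe = vol.affine[:3, :3] @ center + vol.affine[:3, 3]
        probe[axis] = position
        idx = world_to_voxel(vol, probe)[axis]
        return int(round_half_away(idx))
    return int(round_half_away(position))


def extract_slice(scene: Scene, axis: str, position: float,
                  space: str = "image", scale: int = 1) -> np.ndarray:
    """One windowed, colored, blended 2D plane as an RGB uint8 image."""
    ax = AXES[axis] if axis in AXES else int(axis)
    canon = _canonical_scene(scene, space)
    index = _resolve_index(canon, ax, position, space)
    rgb, _ = render_plane(canon, ax, index)
    img = _display_transform(rgb)
    if scale > 1:
        img = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    return img


def _draw_crosshair(img: np.ndarray, fg: np.ndarray, scene: Scene, axis: int,
                    xyz, scale: int) -> None:
    vol = scene.base.volume
    ijk = world_to_voxel(vol, np.asarray(xyz, dtype=float))
    inplane = [a for a in range(3) if a != axis]
    row, col = (int(round_half_away(ijk[a])) for a in inplane)
    h, w = img.shape[0], img.shape[1]
    # display transform swaps + flips: raw (row, col) -> screen (h-1-col, row)
    y = h - 1 - col * scale
    x = row * scale
    if 0 <= y < h:
        img[y, :] = (255, 0, 0)
    if 0 <= x < w:
        img[:, x] = (255, 0, 0)


def compose_mosaic(scene: Scene, spec: MosaicSpec) -> np.ndarray:
    """Lay the requested slices out as a single RGB image."""
    ax = AXES[spec.axis]
    canon = _canonical_scene(scene, spec.space)
    tiles = []
    for pos in spec.slices:
        index = _resolve_index(canon, ax, pos, spec.space)
        rgb, fg = render_plane(canon, ax, index)
        img = _display_transform(rgb)
        m = _display_transform(fg)
        if spec.scale > 1:
            img = np.repeat(np.repeat(img, spec.scale, axis=0), spec.scale, axis=1)
            m = np.repeat(np.repeat(m, spec.scale, axis=0), spec.scale, axis=1)
        if spec.crosshair is not None:
            _draw_crosshair(img, m, canon, ax, spec.crosshair, spec.scale)
        tiles.append((img, m))

    th, tw = tiles[0][0].shape[:2]
    n = len(tiles)
    ncols = min(spec.columns, n)
    nrows = int(np.ceil(n / ncols))
    x_step = int(round(tw * (1.0 - spec.overlap_fraction)))
    width = x_step * (ncols - 1) + tw
    canvas = np.zeros((nrows * th, width, 3), dtype=np.uint8)
    painted = np.zeros((nrows * th, width), dtype=bool)
    for t, (img, fg) in enumerate(tiles):
        row, col = divmod(t, ncols)
        y0, x0 = row * th, col * x_step
        region = canvas[y0:y0 + th, x0:x0 + tw]
        pmask = painted[y0:y0 + th, x0:x0 + tw]
        write = fg | ~pmask  # background is transparent only over earlier tiles
        region[write] = img[write]
        pmask[:] = True
    return canvas


def save_png(image: np.ndarray, path: str | Path) -> Path:
    """Lossless PNG write; reread pixels are identical to the input."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValidationError(
            f"save_png expects 8-bit (uint8) images, got dtype {image.dtype}")
    path = Path(path)
    Image.fromarray(image).save(path, format="PNG")
    return path


def load_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path))
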