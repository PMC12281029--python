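"""Intensity windowing, color lookup tables, translucent blending.

A displayed scene is a stack of :class:`WindowedLayer` objects: a base
anatomical layer plus zero or more overlays (statistical maps, lesion
masks).  Each layer maps voxel intensity to [0, 1] by linear windowing
between its display min/max, then through a 256-entry RGBA LUT.  Overlay
voxels below the overlay's display minimum are fully transparent, so only
supra-threshold values obscure the anatomy underneath.

Also provides the historical 8-bit palette emulation: 255 gray levels for
the anatomical scan plus a single reserved opaque color for the lesion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .volio import Volume


@dataclass
class ColorLUT:
    """A 256-entry RGBA lookup table (channels 0-255)."""

    name: str
    entries: np.ndarray  # (256, 4) uint8

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.uint8)
        if self.entries.shape != (256, 4):
            raise ValidationError(
                f"LUT must have exactly 256 RGBA entries, got shape {self.entries.shape}")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["index", "R", "G", "B", "A"])
            for i, (r, g, b, a) in enumerate(self.entries):
                writer.writerow([i, r, g, b, a])
        return path

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "ColorLUT":
        path = Path(path)
        entries = np.zeros((256, 4), dtype=np.uint8)
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[int(row["index"])] = [row["R"], row["G"], row["B"], row["A"]]
        return cls(name=name or path.stem, entries=entries)


def _ramp_lut(name: str, anchors: list[tuple[float, tuple[int, int, int]]]) -> ColorLUT:
    """Piecewise-linear RGB ramp through (position, color) anchors, alpha 255."""
    pos = np.array([p for p, _ in anchors])
    cols = np.array([c for _, c in anchors], dtype=float)
    x = np.linspace(0.0, 1.0, 256)
    rgb = np.stack([np.interp(x, pos, cols[:, ch]) for ch in range(3)], axis=1)
    entries = np.concatenate([np.round(rgb), np.full((256, 1), 255.0)], axis=1)
    return ColorLUT(name=name, entries=entries.astype(np.uint8))


def _builtin_luts() -> dict[str, ColorLUT]:
    g = np.arange(256, dtype=np.uint8)
    zero = np.zeros(256, dtype=np.uint8)
    full = np.full(256, 255, dtype=np.uint8)
    luts = {
        "grayscale": ColorLUT("grayscale", np.stack([g, g, g, full], axis=1)),
        "red": ColorLUT("red", np.stack([g, zero, zero, full], axis=1)),
        "blue": ColorLUT("blue", np.stack([zero, zero, g, full], axis=1)),
        # warm ramp: black -> red -> yellow -> white
        "hot": _ramp_lut("hot", [(0.0, (0, 0, 0)), (0.375, (255, 0, 0)),
                                 (0.75, (255, 255, 0)), (1.0, (255, 255, 255))]),
        # cold ramp: black -> blue -> cyan -> white
        "cool": _ramp_lut("cool", [(0.0, (0, 0, 0)), (0.375, (0, 0, 255)),
                                   (0.75, (0, 255, 255)), (1.0, (255, 255, 255))]),
        # perceptual dark-violet -> teal -> yellow ramp
        "viridis": _ramp_lut("viridis", [
            (0.0, (68, 1, 84)), (0.25, (59, 82, 139)), (0.5, (33, 145, 140)),
            (0.75, (94, 201, 98)), (1.0, (253, 231, 37))]),
        # cold-to-warm ramp for incidence maps: blue at the low end, red at the top
        "cold_to_warm": _ramp_lut("cold_to_warm", [
            (0.0, (0, 0, 255)), (0.5, (170, 0, 170)), (1.0, (255, 0, 0))]),
    }
    return luts


_LUTS = _builtin_luts()


def get_lut(name: str) -> ColorLUT:
    """Fetch a built-in LUT by name."""
    try:
        return _LUTS[name]
    except KeyError:
        raise ValidationError(
            f"unknown LUT {name!r}; built-ins: {sorted(_LUTS)}") from None


def available_luts() -> list[str]:
    return sorted(_LUTS)


@dataclass
class WindowedLayer:
    """A volume plus its display state: window, LUT, opacity."""

    volume: Volume
    display_min: float
    display_max: float
    lut: ColorLUT = field(default_factory=lambda: get_lut("grayscale"))
    opacity: float = 1.0

    def __post_init__(self) -> None:
        if not self.display_min < self.display_max:
            raise ValidationError(
                f"display_min must be < display_max "
                f"({self.display_min} >= {self.display_max})")
        if not 0.0 <= self.opacity <= 1.0:
            raise ValidationError(f"opacity must be in [0, 1], got {self.opacity}")

    @classmethod
    def auto(cls, volume: Volume, lut: str | ColorLUT = "grayscale",
             opacity: float = 1.0) -> "WindowedLayer":
        """Window over the full data range (a degenerate range widens to 1)."""
        lo = float(np.min(volume.data))
        hi = float(np.max(volume.data))
        if hi <= lo:
            hi = lo + 1.0
        if isinstance(lut, str):
            lut = get_lut(lut)
        return cls(volume=volume, display_min=lo, display_max=hi, lut=lut,
                   opacity=opacity)


@dataclass
class Scene:
    """A base layer plus ordered overlays — the unit montage/render consume."""

    base: WindowedLayer
    overlays: list[WindowedLayer] = field(default_factory=list)

    @property
    def layers(self) -> list[WindowedLayer]:
        return [self.base, *self.overlays]


def window_intensity(value, display_min: float, display_max: float):
    """Linear window to [0, 1] with clamping; scalar or array."""
    if not display_min < display_max:
        raise ValidationError(
            f"display_min must be < display_max ({display_min} >= {display_max})")
    v = np.asarray(value, dtype=np.float64)
    out = np.clip((v - display_min) / (display_max - display_min), 0.0, 1.0)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def apply_lut(normalized, lut: ColorLUT) -> np.ndarray:
    """Map [0, 1] values through a LUT: index = round(value * 255)."""
    norm = np.asarray(normalized, dtype=np.float64)
    idx = np.round(norm * 255.0).astype(np.intp)
    return lut.entries[idx]


def layer_rgba(layer: WindowedLayer, values: np.ndarray,
               transparent_below_min: bool = False) -> np.ndarray:
    """Window + colorize a plane of raw intensities into float RGBA (0-255)."""
    norm = window_intensity(values, layer.display_min, layer.display_max)
    rgba = apply_lut(norm, layer.lut).astype(np.float64)
    if transparent_below_min:
        rgba[..., 3] = np.where(np.asarray(values) < layer.display_min,
                                0.0, rgba[..., 3])
    return rgba


def blend_layers(base_rgb: np.ndarray,
                 overlays: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Source-over composite overlays (RGBA, opacity) onto a base RGB plane.

    All arithmetic is floating point; the result is rounded to uint8 once.
    """
    base = np.asarray(base_rgb, dtype=np.float64)
    out = base[..., :3].copy()
    for rgba, opacity in overlays:
        rgba = np.asarray(rgba, dtype=np.float64)
        if rgba.shape[:-1] != out.shape[:-1]:
            raise ValidationError(
                f"overlay plane shape {rgba.shape[:-1]} != base {out.shape[:-1]}")
        if not 0.0 <= opacity <= 1.0:
            raise ValidationError(f"opacity must be in [0, 1], got {opacity}")
        a = (rgba[..., 3] / 255.0 * opacity)[..., None]
        out = rgba[..., :3] * a + out * (1.0 - a)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def legacy_palette(base: WindowedLayer, lesion, lesion_color=(255, 0, 0)):
    """Emulate the historical 8-bit display: 255 grays + one opaque lesion color.

    Returns ``(indices, palette)`` where ``indices`` matches the base volume
    shape (uint8) and ``palette`` is a (256, 3) uint8 table.  Indices 0-254
    quantize the windowed anatomy to 255 gray levels; index 255 is the
    reserved lesion entry, rendered opaque regardless of the underlying
    intensity — the limitation that precluded translucent lesions.
    """
    mask = np.asarray(lesion.mask if hasattr(lesion, "mask") else lesion) != 0
    if mask.shape != base.volume.shape:
        raise ValidationError(
            f"lesion shape {mask.shape} != base volume shape {base.volume.shape}")
    norm = window_intensity(base.volume.data, base.display_min, base.display_max)
    indices = np.round(norm * 254.0).astype(np.uint8)
    indices[mask] = 255
    gray = np.round(np.arange(255) * 255.0 / 254.0).astype(np.uint8)
    palette = np.zeros((256, 3), dtype=np.uint8)
    palette[:255] = gray[:, None]
    palette[255] = lesion_color
    return indices, palette


def colorbar(lut: ColorLUT, display_min: float, display_max: float,
             size: tuple[int, int] = (24, 128), labels: bool = True) -> np.ndarray:
    """Vertical gradient colorbar (RGB uint8), min at the bottom, max at the top.

    Endpoint labels are drawn when ``labels`` is set and the bar is large
    enough for the bitmap font (>= 16 x 64).
    """
    if not display_min < display_max:
        raise ValidationError("display_min must be < display_max")
    w, h = int(size[0]), int(size[1])
    if w < 1 or h < 2:
        raise ValidationError(f"colorbar size must be >= (1, 2), got {size}")
    rows = np.arange(h)
    norm = 1.0 - rows / (h - 1)  # top row = display_max
    idx = np.round(norm * 255.0).astype(np.intp)
    img = np.repeat(lut.entries[idx, :3][:, None, :], w, axis=1).astype(np.uint8)
    if labels and w >= 16 and h >= 64:
        from PIL import Image, ImageDraw
        pil = Image.fromarray(img)
        draw = ImageDraw.Draw(pil)
        top_gray = int(np.mean(img[0]))
        bot_gray = int(np.mean(img[-1]))
        draw.text((1, 1), f"{display_max:g}",
                  fill=(0, 0, 0) if top_gray > 127 else (255, 255, 255))
        draw.text((1, h - 11), f"{display_min:g}",
                  fill=(0, 0, 0) if bot_gray > 127 else (255, 255, 255))
        img = np.asarray(pil)
    return img
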