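"""Rudimentary CPU volume rendering: orthographic ray casting.

Rays are cast through the canonical RAS volume at the requested azimuth
and elevation, sampling trilinearly at a fixed millimetre step.  Two modes:

* ``mip`` — keep the maximum windowed intensity along each ray, then color
  through the layer LUT;
* ``composite`` — front-to-back alpha accumulation with per-sample alpha
  equal to windowed intensity times ``opacity_gain``, terminating once the
  accumulated alpha reaches 0.99.

An optional axis-aligned cut-out box removes a block of voxels from the
rendering; :func:`hybrid_render` textures the exposed interior faces of
that box with the corresponding 2D slices, combining the 3D overview with
2D slice precision.

The projection is orthographic and there is no gradient shading — the
transfer function is simply the windowed intensity scaled by the gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .layers import Scene, apply_lut, layer_rgba, window_intensity
from .montage import _canonical_scene, render_plane
from .spatial import _sample_array, voxel_to_world

Box = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


@dataclass
class RenderSpec:
    """Declarative description of one rendered view."""

    azimuth: float = 45.0
    elevation: float = 20.0
    mode: str = "composite"
    step_mm: float = 1.0
    opacity_gain: float = 0.1
    cutout: Optional[Box] = None
    image_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.mode not in ("mip", "composite"):
            raise ValidationError(f"mode must be mip or composite, got {self.mode!r}")
        if self.step_mm <= 0:
            raise ValidationError(f"step_mm must be positive, got {self.step_mm}")
        if not 0.0 < self.opacity_gain <= 1.0:
            raise ValidationError(
                f"opacity_gain must be in (0, 1], got {self.opacity_gain}")
        if any(int(s) < 1 for s in self.image_size):
            raise ValidationError(f"image_size must be positive, got {self.image_size}")
        if self.cutout is not None:
            box = tuple((float(lo), float(hi)) for lo, hi in self.cutout)
            for lo, hi in box:
                if hi < lo:
                    raise ValidationError(f"cutout bounds {self.cutout} are inverted")
            self.cutout = box  # type: ignore[assignment]


def _view_basis(azimuth: float, elevation: float):
    az, el = np.radians(azimuth), np.radians(elevation)
    eye = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    f = -eye  # forward, unit
    u = np.array([-np.sin(az), np.cos(az), 0.0])  # right (horizontal)
    v = np.cross(u, f)  # up on the image
    return f, u, v


def _ray_box(o: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Slab intersection.  o: (3, N), d: (3,).  Returns t0, t1, entry_axis."""
    n = o.shape[1]
    t0 = np.full(n, -np.inf)
    t1 = np.full(n, np.inf)
    entry_axis = np.zeros(n, dtype=np.int8)
    for a in range(3):
        if abs(d[a]) < 1e-12:
            outside = (o[a] < lo[a]) | (o[a] > hi[a])
            t0 = np.where(outside, np.inf, t0)
            continue
        ta = (lo[a] - o[a]) / d[a]
        tb = (hi[a] - o[a]) / d[a]
        near, far = np.minimum(ta, tb), np.maximum(ta, tb)
        entry_axis = np.where(near > t0, np.int8(a), entry_axis)
        t0 = np.maximum(t0, near)
        t1 = np.minimum(t1, far)
    return t0, t1, entry_axis


def _cutout_empty(box: Optional[Box]) -> bool:
    return box is None or any(hi <= lo for lo, hi in box)


def raycast(scene: Scene, spec: RenderSpec,
            return_alpha: bool = False) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Render the scene; optionally also return the accumulated alpha plane."""
    return _cast(scene, spec, reveal=None, return_alpha=return_alpha)


def hybrid_render(scene: Scene, spec: RenderSpec,
                  reveal_layers_in_cutout: bool = True) -> np.ndarray:
    """Ray casting with the cut-out's exposed interior faces slice-textured."""
    if spec.cutout is None:
        raise ValidationError("hybrid_render requires a cutout box in the spec")
    return _cast(scene, spec, reveal=bool(reveal_layers_in_cutout))


def _cast(scene: Scene, spec: RenderSpec, reveal: Optional[bool],
          return_alpha: bool = False):
    if scene.base is None:
        raise ValidationError("render needs a scene with at least a base layer")
    canon = _canonical_scene(scene, "image")
    vol = canon.base.volume
    shape = np.asarray(vol.shape, dtype=float)
    A = vol.affine
    Ainv = np.linalg.inv(A)

    corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                        for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)])
    world_corners = voxel_to_world(vol, corners.astype(float))
    center = world_corners.mean(axis=0)
    extent = float(np.linalg.norm(world_corners.max(0) - world_corners.min(0)))
    extent = max(extent, 1e-6)

    f, u, v = _view_basis(spec.azimuth, spec.elevation)
    W, H = int(spec.image_size[0]), int(spec.image_size[1])
    s = extent / min(W, H)
    px = (np.arange(W) - (W - 1) / 2.0) * s
    py = ((H - 1) / 2.0 - np.arange(H)) * s
    PX, PY = np.meshgrid(px, py)  # (H, W)
    origins = (center[:, None]
               + np.outer(u, PX.ravel()) + np.outer(v, PY.ravel())
               - f[:, None] * extent)  # start well behind the volume
    N = origins.shape[1]

    o_v = Ainv[:3, :3] @ origins + Ainv[:3, 3:4]
    d_v = Ainv[:3, :3] @ f  # t stays in world mm since f is unit-length

    lo = np.full(3, -0.5)
    hi = shape - 0.5
    t0, t1, _ = _ray_box(o_v, d_v, lo, hi)
    hits = t0 < t1

    box = None if _cutout_empty(spec.cutout) else spec.cutout
    if box is not None:
        blo = np.array([b[0] for b in box]) - 0.5
        bhi = np.array([b[1] for b in box]) - 0.5
        tb0, tb1, b_axis = _ray_box(o_v, d_v, blo, bhi)
        box_hit = (tb0 < tb1) & hits
    face_tex = None
    if box is not None and reveal is not None:
        tex_scene = canon if reveal else Scene(base=canon.base)
        face_tex = []
        for a in range(3):
            idx = int(box[a][0]) if d_v[a] > 0 else int(box[a][1]) - 1
            idx = int(np.clip(idx, 0, vol.shape[a] - 1))
            rgb, _ = render_plane(tex_scene, a, idx)
            face_tex.append((idx, rgb.astype(np.float64)))

    step = float(spec.step_mm)
    span = np.where(hits, t1 - t0, 0.0)
    K = int(np.ceil(span.max() / step)) if hits.any() else 0

    layers = canon.layers
    datas = [np.asarray(l.volume.data, dtype=np.float64) for l in layers]

    if spec.mode == "mip":
        maxima = [np.full(N, -np.inf) for _ in layers]
        sampled = np.zeros(N, dtype=bool)
        for n in range(K):
            t = t0 + (n + 0.5) * step
            active = hits & (t <= t1)
            if not active.any():
                break
            pos = o_v[:, active] + t[active] * d_v[:, None]
            keep = np.ones(pos.shape[1], dtype=bool)
            if box is not None:
                inside = np.all((pos >= blo[:, None]) & (pos < bhi[:, None]), axis=0)
                keep = ~inside
            if not keep.any():
                continue
            sel = np.flatnonzero(active)[keep]
            sampled[sel] = True
            for li, data in enumerate(datas):
                vals = _sample_array(data, pos[:, keep], "trilinear")
                maxima[li][sel] = np.maximum(maxima[li][sel], vals)
        out = np.zeros((N, 3), dtype=np.float64)
        base_vals = np.where(sampled, maxima[0], 0.0)
        base_rgba = layer_rgba(layers[0], base_vals)
        out[sampled] = base_rgba[sampled, :3]
        for li, ov in enumerate(layers[1:], start=1):
            vals = np.where(sampled, maxima[li], -np.inf)
            vis = sampled & (vals >= ov.display_min)
            rgba = layer_rgba(ov, np.where(np.isfinite(vals), vals, 0.0),
                              transparent_below_min=True)
            a = (rgba[:, 3] / 255.0 * ov.opacity) * vis
            out = rgba[:, :3] * a[:, None] + out * (1.0 - a[:, None])
        img = np.clip(np.round(out), 0, 255).astype(np.uint8).reshape(H, W, 3)
        if return_alpha:
            return img, sampled.astype(np.float64).reshape(H, W)
        return img

    # composite mode
    acc_rgb = np.zeros((N, 3), dtype=np.float64)
    acc_a = np.zeros(N, dtype=np.float64)
    done = ~hits
    face_done = np.zeros(N, dtype=bool)
    for n in range(K):
        t = t0 + (n + 0.5) * step
        active = ~done & (t <= t1)
        if not active.any():
            break
        if face_tex is not None:
            hit_face = active & box_hit & (t >= tb0) & ~face_done
            if hit_face.any():
                idxs = np.flatnonzero(hit_face)
                p_entry = o_v[:, idxs] + tb0[idxs] * d_v[:, None]
                for a in range(3):
                    sub = idxs[b_axis[idxs] == a]
                    if len(sub) == 0:
                        continue
                    _, tex = face_tex[a]
                    inplane = [ax for ax in range(3) if ax != a]
                    pe = o_v[:, sub] + tb0[sub] * d_v[:, None]
                    r = np.clip(np.round(pe[inplane[0]]), 0, tex.shape[0] - 1).astype(int)
                    c = np.clip(np.round(pe[inplane[1]]), 0, tex.shape[1] - 1).astype(int)
                    color = tex[r, c]
                    w = (1.0 - acc_a[sub])[:, None]
                    acc_rgb[sub] += w * color
                    acc_a[sub] = 1.0
                face_done[idxs] = True
                done[idxs] = True
                active = active & ~hit_face
            if not active.any():
                continue
        pos = o_v[:, active] + t[active] * d_v[:, None]
        alpha_keep = np.ones(pos.shape[1], dtype=bool)
        if box is not None:
            inside = np.all((pos >= blo[:, None]) & (pos < bhi[:, None]), axis=0)
            alpha_keep = ~inside
        base_vals = _sample_array(datas[0], pos, "trilinear")
        norm = window_intensity(base_vals, layers[0].display_min, layers[0].display_max)
        c = apply_lut(norm, layers[0].lut)[:, :3].astype(np.float64)
        a = norm * spec.opacity_gain * layers[0].opacity
        for li, ov in enumerate(layers[1:], start=1):
            vals = _sample_array(datas[li], pos, "trilinear")
            normo = window_intensity(vals, ov.display_min, ov.display_max)
            co = apply_lut(normo, ov.lut)[:, :3].astype(np.float64)
            ao = normo * spec.opacity_gain * ov.opacity
            ao = np.where(vals < ov.display_min, 0.0, ao)
            c = co * ao[:, None] + c * (1.0 - ao[:, None])
            a = ao + a * (1.0 - ao)
        a = a * alpha_keep
        sel = np.flatnonzero(active)
        w = (1.0 - acc_a[sel]) * a
        acc_rgb[sel] += w[:, None] * c
        acc_a[sel] += w
        done[sel[acc_a[sel] >= 0.99]] = True
    img = np.clip(np.round(acc_rgb), 0, 255).astype(np.uint8).reshape(H, W, 3)
    if return_alpha:
        return img, acc_a.reshape(H, W)
    return img
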