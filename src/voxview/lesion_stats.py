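"""Group lesion incidence maps and per-VOI descriptive statistics.

An incidence map gives, per voxel, the fraction of subjects whose binary
lesion mask covers that voxel.  Display follows the conventional
cold-to-warm thresholding: fractions at or below the low threshold
(default 1%) are transparent, fractions at or above the high threshold
(default 10%) saturate at the warm end of the ramp.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .layers import ColorLUT, WindowedLayer, get_lut
from .spatial import GridSpec, voxel_to_world
from .voi_draw import VOI
from .volio import Volume, volume_from_array


@dataclass
class IncidenceMap:
    """Per-voxel lesion fraction across a group of subjects."""

    fraction: np.ndarray
    n_subjects: int
    geometry: GridSpec

    def to_volume(self) -> Volume:
        return volume_from_array(self.fraction.astype(np.float32),
                                 affine=self.geometry.affine,
                                 datatype="float32", source_format="synthetic")


def incidence_map(vois: list[VOI]) -> IncidenceMap:
    """Mean of binary masks over subjects; inputs must share one grid.

    Mismatched grids are rejected rather than silently resliced: reslice
    binary masks explicitly (nearest-neighbour) first.
    """
    if not vois:
        raise ValidationError("incidence_map needs at least one VOI")
    ref = vois[0]
    for idx, voi in enumerate(vois[1:], start=1):
        if voi.shape != ref.shape:
            raise ValidationError(
                f"VOI #{idx} shape {voi.shape} != reference shape {ref.shape}")
        if np.max(np.abs(voi.affine - ref.affine)) > 1e-3:
            raise ValidationError(
                f"VOI #{idx} affine differs from the reference by more than 1e-3 mm")
    counts = np.zeros(ref.shape, dtype=np.int64)
    for voi in vois:
        counts += voi.mask
    fraction = counts / float(len(vois))
    return IncidenceMap(fraction=fraction, n_subjects=len(vois),
                        geometry=GridSpec(shape=ref.shape, affine=ref.affine))


def incidence_overlay(imap: IncidenceMap, low_threshold: float = 0.01,
                      high_threshold: float = 0.10,
                      lut: ColorLUT | None = None) -> WindowedLayer:
    """Windowed overlay layer: transparent below ``low``, warm end at ``high``."""
    if not 0.0 <= low_threshold < high_threshold <= 1.0:
        raise ValidationError(
            f"need 0 <= low < high <= 1, got ({low_threshold}, {high_threshold})")
    if lut is None:
        lut = get_lut("cold_to_warm")
    return WindowedLayer(volume=imap.to_volume(), display_min=low_threshold,
                         display_max=high_threshold, lut=lut, opacity=1.0)


_CSV_COLUMNS = ("label", "n_voxels", "volume_mm3",
                "com_x_mm", "com_y_mm", "com_z_mm",
                "bbox_min_x_mm", "bbox_min_y_mm", "bbox_min_z_mm",
                "bbox_max_x_mm", "bbox_max_y_mm", "bbox_max_z_mm")


def voi_descriptives(voi: VOI, label: str = "") -> dict[str, object]:
    """Voxel count, volume in mm^3, world center of mass and world bounding box.

    An empty VOI yields n_voxels 0 with NaN centroid/bbox (flagged undefined).
    """
    idx = np.argwhere(voi.mask != 0)
    n = int(len(idx))
    vox_mm3 = abs(float(np.linalg.det(voi.affine[:3, :3])))
    rec: dict[str, object] = {"label": label, "n_voxels": n,
                              "volume_mm3": n * vox_mm3}
    if n == 0:
        for key in _CSV_COLUMNS[3:]:
            rec[key] = float("nan")
        return rec
    world = voxel_to_world(GridSpec(shape=voi.shape, affine=voi.affine),
                           idx.astype(float))
    com = world.mean(axis=0)
    lo, hi = world.min(axis=0), world.max(axis=0)
    rec.update(com_x_mm=float(com[0]), com_y_mm=float(com[1]), com_z_mm=float(com[2]),
               bbox_min_x_mm=float(lo[0]), bbox_min_y_mm=float(lo[1]),
               bbox_min_z_mm=float(lo[2]), bbox_max_x_mm=float(hi[0]),
               bbox_max_y_mm=float(hi[1]), bbox_max_z_mm=float(hi[2]))
    return rec


def write_descriptives_csv(records: list[dict[str, object]],
                           path: str | Path) -> Path:
    """One headered row per VOI, fixed column order, reread-stable floats."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.get("label", ""), rec["n_voxels"],
                *(repr(float(rec[c])) for c in _CSV_COLUMNS[2:]),
            ])
    return path
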