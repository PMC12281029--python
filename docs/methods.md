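# Methods

This note records the conventions, models and numerical choices behind
voxview, and what the synthetic test data do and do not establish.

## Coordinate model

A `Volume` is a 3D array indexed `data[i, j, k]` plus a 4×4 voxel→world
affine in RAS+ millimetres. Indices are 0-based and address voxel
*centers*: world = `A @ (i, j, k, 1)`. When a NIfTI header carries both
transforms, the sform takes precedence over the qform; when both codes are
zero the reader falls back to diagonal pixdim scaling and logs a warning
(common practice; header-only files give no better information).

The qform is decoded with the standard quaternion formula including the
`qfac` sign, and encoded by snapping the normalized direction-cosine
matrix to the nearest rotation (SVD) before extracting the quaternion, so
shear or round-off in an input affine cannot produce an invalid header.

Format-specific affine construction:

* **MGH/MGZ** — direction cosines `Mdc` scaled by spacing, anchored at the
  center voxel `Pxyz_c` (MGH is always big-endian; `.mgz` is the gzipped
  byte stream).
* **AFNI** — `ORIENT_SPECIFIC`/`ORIGIN`/`DELTA` interpreted in AFNI's
  DICOM-ordered frame (+x Left, +y Posterior, +z Superior) and negated on
  x/y to produce RAS. All 48 orientation codes are accepted on read; the
  writer emits axis-aligned grids only, since that is all the attribute
  triple can represent. `BRICK_FLOAT_FACS` scale factors are applied when
  nonzero; only sub-brick 0 is loaded.
* **NRRD** — `space directions` columns + `space origin`, with LPS/LAS
  spaces flipped into RAS. Only attached-data, raw or gzip, 3D scalar
  files are supported; detached headers are rejected with a clear error.
* **VTK legacy** — `ORIGIN` + `SPACING` diagonal; STRUCTURED_POINTS only,
  BINARY (big-endian, per the format) or ASCII scalars.

Every format stores voxels i-fastest, so all serialization uses Fortran
order against the `[i, j, k]` array.

## Sampling and reslicing

Nearest-neighbour lookup rounds half away from zero — one documented rule
applied identically in every module (sampling, mm→slice-index mapping,
crosshair placement). Trilinear interpolation is the weighted average of
the 8 surrounding voxel centers (delegated to
`scipy.ndimage.map_coordinates`, order 1). Coordinates outside the grid —
beyond the voxel-center extent `[0, n−1]` — return 0, a hard background
fill rather than edge clamping: lesion maps and statistical overlays must
not smear their border values outward. A consequence used by the tests:
an axis-aligned ray through a uniform cube accumulates exactly one sample
per in-grid sample position, so composite opacity follows
`1 − (1 − a)^k` with `k` countable in closed form.

`canonical_ras` reorients losslessly: the voxel-axis → world-axis
assignment is solved as a linear assignment on |R| (robust even for
oblique affines), then axes are permuted and flipped so the 3×3 part has a
positive diagonal. No interpolation occurs; every voxel keeps its world
position to machine precision, and the operation is idempotent.

*Image space* display shows the raw grid, one square screen block per
voxel — anisotropy stays visible, which is the point when tracing lesions
on acquired slices. *World space* display reslices the whole scene
trilinearly onto an isotropic grid whose spacing is the smallest source
voxel dimension, covering the volume's world bounding box.

## Display model

Windowing is `clamp((v − min)/(max − min), 0, 1)`; LUT lookup uses
`round(value·255)`. Compositing is source-over in floating point with a
single final rounding to 8 bits, avoiding cumulative quantization.
Overlay voxels below the overlay's display minimum get alpha 0, so
statistical maps show only supra-threshold voxels over anatomy.

Built-in LUTs (grayscale, red, blue, hot, cool, a viridis-like perceptual
ramp, and a cold-to-warm ramp for incidence maps) are piecewise-linear
ramps defined in `layers.py` and serializable as 256-line CSV. They are
documented replacements, not reproductions of any particular historical
color tables, which were never published.

The legacy-palette emulation quantizes windowed anatomy to 255 gray
levels (indices 0–254) and reserves index 255 for the lesion, rendered
opaque regardless of the underlying intensity — reproducing the
historical 8-bit constraint that precluded translucent lesions.

Colorbar endpoint labels are drawn with Pillow's bitmap font only when
the bar is at least 16×64 pixels; smaller bars are valid but unlabeled.

## Mosaics

Slice lists are arbitrary (not necessarily equidistant); positions in mm
are mapped to indices through `world_to_voxel` and the rounding rule.
Tiles are laid out row-major; horizontal placement advances by
`round(tile_width · (1 − overlap))`. In the overlapped strip, later
slices paint over earlier ones with zero-intensity background treated as
transparent — later tiles never punch black holes into their neighbours.
The overlap fraction is a free parameter (0–0.9).

## Volume rendering

Projection is orthographic: sufficient for static figures, and the
simplest model that keeps ray spacing uniform. Rays are generated on a
square-pixel image plane scaled so the volume's world-space diagonal fits
the smaller image dimension, intersected with the volume's voxel bounding
box by the slab method, and sampled trilinearly starting half a step
inside the entry face. MIP tracks the per-layer maximum raw intensity
(windowing is monotone, so windowing the maximum afterwards is exact).
Composite mode accumulates front-to-back with per-sample alpha = windowed
intensity × `opacity_gain` (default 0.1 — roughly 20 samples to reach
~90% opacity at full intensity, a reasonable scale for millimetre steps
through a head-sized volume); rays terminate at accumulated alpha 0.99.
The transfer function is a documented stand-in — the original tool's was
never published — and there is no gradient shading, matching the
"rudimentary" scope of the original CPU renderer.

The cut-out box removes an axis-aligned block (half-open voxel bounds).
In hybrid mode a ray that reaches the box composites the texel of the 2D
slice at the box face it entered through, fully opaque, and terminates —
which is exactly how a slice cut-out figure reads: 3D context outside,
2D slice precision on the exposed faces. A zero-extent box degenerates to
plain ray casting.

## Lesion drawing and the RLE codec

Drawing operates in image space, slice by slice (interpolating a binary
mask would alias its boundary). The pen paints voxels whose center lies
within thickness/2 of the polyline (Euclidean, in-plane); ellipse
membership is the inscribed-ellipse inequality at voxel centers, with the
outline defined as filled minus its 4-connected erosion. Bucket fill is
4-connected so that 8-connected drawn contours are watertight. Intensity
growing takes the 3D connected component (6- or 26-connectivity) of the
thresholded volume containing the seed. Morphology uses a discrete
Euclidean ball. All operators return new VOIs and touch only the
addressed slice (3D operations excepted).

`.voi` files are gzipped uint8 NIfTI-1 with the reference affine, written
with a fixed gzip mtime so identical masks produce identical bytes.

The legacy ROI codec stores, per slice, row-major (start, length) runs of
set pixels in 16-bit fields, which caps slices at 65536 in-plane pixels —
encoding a 256×256 slice succeeds, 256×257 is refused with a capacity
error naming the limit. A maximal run of 65536 pixels cannot fit one
16-bit length, so the encoder splits runs longer than 65535 into adjacent
runs; every stored field stays 16-bit while the full 65536-pixel plane
remains encodable. The on-disk dialect (magic `MRO1`, plane dims, then
per-slice index/run-count/pairs, little-endian) is defined and documented
here as a faithful-capacity reconstruction; bit-compatibility with
historical archive files is explicitly not claimed, since their byte
layout (including row- vs column-major flattening) was never published.

## Incidence maps

The incidence map is the per-voxel mean of binary masks; inputs on
mismatched grids (affine difference > 1e-3 mm) are rejected rather than
silently resliced — hidden interpolation of binary data is never
acceptable. The default overlay thresholds, transparent at 1% and
saturated at 10%, follow the conventional display of group lesion maps;
the cold-to-warm ramp is a documented substitute for unpublished
originals.

## Synthetic data

The fixtures module paints geometric primitives (spheres, boxes, linear
ramps) in listed order — later primitives overwrite earlier — then adds
Gaussian noise from NumPy's PCG64 generator seeded by the spec, so
identical spec + seed reproduces bit-identical voxels. Sphere membership
is voxel-center distance ≤ radius, inclusive, avoiding boundary
ambiguity. Noise is clamped to the datatype range only at serialization,
keeping float fixtures exact in memory. The default phantom is a
32×32×24 grid with 1×1×1.5 mm voxels, a bright shell with interior
structure and σ=2 noise — small enough for fast tests, structured enough
to exercise windowing, overlays and rendering. Lesion sets are random
spheres (radius 2–5 voxels) constrained to fit the grid.

These phantoms exercise every code path (formats, geometry, blending,
drawing, incidence) but are not anatomy: no bias fields, motion, partial
voluming or realistic lesion shapes. Passing tests establish the
correctness of the arithmetic and the file formats, not segmentation
quality on clinical data.

## Verification strategy

Geometry and drawing operators are tested against independent brute-force
oracles (exhaustive voxel scans, BFS flood fills, closed-form compositing)
rather than against themselves; file formats are tested by round-trip
identity across all format pairs and, for NIfTI/MGH/AFNI, against an
independent established reader (nibabel) in the test suite only. Problem
sizes in tests (phantoms ≤ 32³, renders ≤ 64², 100–1000 randomized
oracle trials) were chosen to keep the full suite in the low seconds
while still exhausting each operator's decision structure.

## Known limitations

* NIfTI-2, CIFTI, DICOM, ECAT, BrainVoyager and BVOX are out of scope;
  DICOM conversion belongs to dedicated converters.
* NRRD support is deliberately a strict subset (attached 3D scalar data).
* The AFNI writer requires axis-aligned affines; oblique datasets can be
  read (via their orientation codes) but not written.
* Rendering is orthographic, unshaded and non-interactive by design.
* The legacy ROI dialect is capacity-faithful, not bit-compatible.
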