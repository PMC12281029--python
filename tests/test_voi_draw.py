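import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import nibabel as nib

from voxview import (VOI, CapacityError, ValidationError, bucket_fill,
                     draw_ellipse, intensity_grow, load_voi, morph, pen_stroke,
                     rle_decode_slice, rle_encode_slice, save_voi,
                     volume_from_array)
from voxview.voi_draw import (LegacyRoiSlice, copy_slice, load_roi,
                              paste_slice, save_roi)


def _voi(shape=(16, 16, 8)):
    return VOI.empty(shape, np.eye(4))


def _slice_hashes(voi, skip, axis=2):
    return [hashlib.sha256(np.take(voi.mask, k, axis=axis).tobytes()).hexdigest()
            for k in range(voi.shape[axis]) if k != skip]


class TestPenStroke:
    def test_horizontal_line_thickness_one(self):
        voi = pen_stroke(_voi(), 3, [(5, 2), (5, 6)], thickness=1)
        assert int(voi.mask.sum()) == 5
        assert np.all(voi.mask[5, 2:7, 3] == 1)

    def test_draw_then_erase_is_empty(self):
        voi = pen_stroke(_voi(), 3, [(5, 2), (9, 6)], thickness=3)
        voi = pen_stroke(voi, 3, [(5, 2), (9, 6)], thickness=3, erase=True)
        assert not voi.mask.any()

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_point_to_segment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 15, size=(3, 2))
        thickness = float(rng.uniform(1, 4))
        voi = pen_stroke(_voi(), 2, pts, thickness=thickness)
        r = thickness / 2.0
        expected = np.zeros((16, 16), dtype=bool)
        for y in range(16):
            for x in range(16):
                p = np.array([y, x], dtype=float)
                for a, b in zip(pts[:-1], pts[1:]):
                    ab = b - a
                    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
                    if np.linalg.norm(p - (a + t * ab)) <= r + 1e-12:
                        expected[y, x] = True
        assert np.array_equal(voi.mask[:, :, 2].astype(bool), expected)

    def test_only_addressed_slice_touched(self):
        before = _slice_hashes(_voi(), skip=4)
        voi = pen_stroke(_voi(), 4, [(3, 3), (10, 10)], thickness=5)
        assert _slice_hashes(voi, skip=4) == before

    def test_out_of_range_slice_rejected(self):
        with pytest.raises(ValidationError):
            pen_stroke(_voi(), 99, [(0, 0)])


class TestEllipse:
    @pytest.mark.parametrize("r", [2, 3, 5])
    def test_circle_count_matches_brute_force(self, r):
        c = 8
        voi = draw_ellipse(_voi((20, 20, 4)), 1, ((c - r, c - r), (c + r, c + r)))
        expected = sum(1 for y in range(20) for x in range(20)
                       if (y - c) ** 2 + (x - c) ** 2 <= r ** 2)
        assert int(voi.mask[:, :, 1].sum()) == expected

    def test_outline_is_filled_minus_erosion(self):
        box = ((3, 4), (12, 14))
        filled = draw_ellipse(_voi(), 0, box).mask[:, :, 0].astype(bool)
        outline = draw_ellipse(_voi(), 0, box, filled=False).mask[:, :, 0].astype(bool)
        eroded = ndimage.binary_erosion(
            filled, structure=ndimage.generate_binary_structure(2, 1))
        assert np.array_equal(outline, filled & ~eroded)

    def test_erase_over_identical_ellipse_empties(self):
        box = ((2, 2), (10, 12))
        voi = draw_ellipse(_voi(), 5, box)
        voi = draw_ellipse(voi, 5, box, erase=True)
        assert not voi.mask.any()

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValidationError):
            draw_ellipse(_voi(), 0, ((3, 3), (3, 9)))


class TestBucketFill:
    def test_fill_inside_closed_circle(self):
        voi = draw_ellipse(_voi(), 2, ((3, 3), (13, 13)), filled=False)
        boundary = voi.mask[:, :, 2].copy()
        voi = bucket_fill(voi, 2, (8, 8))
        filled = draw_ellipse(_voi(), 2, ((3, 3), (13, 13))).mask[:, :, 2]
        # interior + boundary = the filled ellipse; exterior untouched
        assert np.array_equal(voi.mask[:, :, 2] | boundary, filled | boundary)
        assert voi.mask[0, 0, 2] == 0

    def test_seed_outside_contour_fills_background(self):
        voi = draw_ellipse(_voi(), 1, ((5, 5), (11, 11)), filled=False)
        voi = bucket_fill(voi, 1, (0, 0))
        inside = draw_ellipse(_voi(), 1, ((5, 5), (11, 11))).mask[:, :, 1]
        eroded_inside = inside & ~voi.mask[:, :, 1]
        assert voi.mask[0, 0, 1] == 1
        assert eroded_inside.any()  # strict interior stays unfilled

    def test_seed_on_set_voxel_is_noop(self):
        voi = pen_stroke(_voi(), 0, [(4, 4)])
        out = bucket_fill(voi, 0, (4, 4))
        assert np.array_equal(out.mask, voi.mask)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        plane = (rng.random((12, 12)) < 0.35).astype(np.uint8)
        free = np.argwhere(plane == 0)
        sy, sx = free[rng.integers(len(free))]
        voi = VOI.empty((12, 12, 2), np.eye(4))
        voi.mask[:, :, 0] = plane
        out = bucket_fill(voi, 0, (sy, sx), axis=2)
        # breadth-first search reference
        seen = {(int(sy), int(sx))}
        frontier = [(int(sy), int(sx))]
        while frontier:
            y, x = frontier.pop()
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if (0 <= ny < 12 and 0 <= nx < 12 and not plane[ny, nx]
                        and (ny, nx) not in seen):
                    seen.add((ny, nx))
                    frontier.append((ny, nx))
        expected = plane.copy()
        for y, x in seen:
            expected[y, x] = 1
        assert np.array_equal(out.mask[:, :, 0], expected)


class TestIntensityGrow:
    def _two_blob_volume(self):
        data = np.zeros((12, 12, 12), dtype=np.float32)
        data[2:5, 2:5, 2:5] = 50.0
        data[8:11, 8:11, 8:11] = 50.0
        return volume_from_array(data)

    def test_uniform_volume_full_range_selects_all(self):
        vol = volume_from_array(np.full((6, 6, 6), 5.0, dtype=np.float32))
        voi = intensity_grow(vol, (0, 0, 0), 0.0, 10.0)
        assert voi.mask.all()

    def test_only_seeded_blob_selected(self):
        vol = self._two_blob_volume()
        voi = intensity_grow(vol, (3, 3, 3), 40.0, 60.0)
        assert voi.mask[3, 3, 3] == 1
        assert voi.mask[9, 9, 9] == 0
        assert int(voi.mask.sum()) == 27

    def test_seed_outside_range_rejected(self):
        vol = self._two_blob_volume()
        with pytest.raises(ValidationError):
            intensity_grow(vol, (0, 0, 0), 40.0, 60.0)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        data = (rng.random((8, 8, 8)) < 0.4).astype(np.float32)
        seeds = np.argwhere(data > 0)
        seed = tuple(int(x) for x in seeds[0])
        vol = volume_from_array(data)
        voi = intensity_grow(vol, seed, 0.5, 1.5, connectivity=connectivity)
        struct = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
        labels, _ = ndimage.label(data > 0.5, structure=struct)
        assert np.array_equal(voi.mask, (labels == labels[seed]).astype(np.uint8))


class TestMorph:
    def _blob(self):
        voi = _voi((12, 12, 12))
        voi.mask[4:8, 4:8, 4:8] = 1
        return voi

    def test_extensivity(self):
        voi = self._blob()
        assert (morph(voi, "dilate", 1).mask >= voi.mask).all()
        assert (morph(voi, "erode", 1).mask <= voi.mask).all()

    def test_close_idempotent(self):
        rng = np.random.default_rng(5)
        voi = _voi((12, 12, 12))
        voi.mask[:] = (rng.random((12, 12, 12)) < 0.3)
        once = morph(voi, "close", 1)
        twice = morph(once, "close", 1)
        assert np.array_equal(once.mask, twice.mask)

    def test_single_voxel_radius1_ball_is_7(self):
        voi = _voi((9, 9, 9))
        voi.mask[4, 4, 4] = 1
        out = morph(voi, "dilate", 1)
        assert int(out.mask.sum()) == 7  # 6-neighbour ball plus center


class TestCopyPaste:
    def test_copy_paste_identity_and_no_aliasing(self):
        voi = draw_ellipse(_voi(), 2, ((2, 2), (10, 10)))
        buf = copy_slice(voi, 2)
        same = paste_slice(voi, 2, buf)
        assert np.array_equal(same.mask, voi.mask)
        pasted = paste_slice(voi, 5, buf)
        assert np.array_equal(pasted.mask[:, :, 5], voi.mask[:, :, 2])
        buf[:] = 0  # mutating the buffer must not reach back
        assert pasted.mask[:, :, 5].any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paste_slice(_voi(), 0, np.zeros((3, 3)))


class TestVoiFiles:
    def test_roundtrip_and_gzip_magic(self, tmp_path, phantom):
        voi = VOI.on_grid(phantom)
        voi.mask[5:10, 5:10, 5:10] = 1
        p = save_voi(voi, tmp_path / "lesion.voi")
        assert p.read_bytes()[:2] == b"\x1f\x8b"
        back = load_voi(p)
        assert np.array_equal(back.mask, voi.mask)
        assert np.max(np.abs(back.affine - voi.affine)) < 1e-4

    def test_renamed_voi_opens_in_independent_reader(self, tmp_path, phantom):
        voi = VOI.on_grid(phantom)
        voi.mask[2:6, 3:7, 4:8] = 1
        p = save_voi(voi, tmp_path / "lesion.voi")
        renamed = tmp_path / "lesion.nii.gz"
        renamed.write_bytes(p.read_bytes())
        img = nib.load(str(renamed))
        assert np.array_equal(np.asarray(img.dataobj), voi.mask)


class TestRLE:
    def test_empty_plane_zero_runs(self):
        rle = rle_encode_slice(np.zeros((10, 10)))
        assert rle.runs == []

    def test_all_ones_10x10_single_run(self):
        rle = rle_encode_slice(np.ones((10, 10)))
        assert rle.runs == [(0, 100)]

    def test_capacity_limit_is_65536_pixels(self):
        plane = np.ones((256, 256), dtype=np.uint8)
        rle = rle_encode_slice(plane)
        assert np.array_equal(rle_decode_slice(rle, (256, 256)), plane)
        with pytest.raises(CapacityError, match="65536"):
            rle_encode_slice(np.zeros((256, 257)))

    def test_all_stored_fields_fit_16_bits(self):
        rle = rle_encode_slice(np.ones((256, 256)))
        assert all(0 <= s <= 0xFFFF and 1 <= ln <= 0xFFFF for s, ln in rle.runs)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 40), st.integers(1, 40))
    def test_roundtrip_identity_random_masks(self, seed, h, w):
        rng = np.random.default_rng(seed)
        plane = (rng.random((h, w)) < 0.4).astype(np.uint8)
        rle = rle_encode_slice(plane)
        assert np.array_equal(rle_decode_slice(rle, (h, w)), plane)
        # runs sorted and non-overlapping
        prev_end = -1
        for s, ln in rle.runs:
            assert s >= prev_end
            prev_end = s + ln

    def test_corrupt_run_rejected(self):
        with pytest.raises(Exception, match="exceeds"):
            rle_decode_slice(LegacyRoiSlice(0, [(95, 10)]), (10, 10))

    def test_legacy_roi_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(11)
        voi = _voi((20, 18, 6))
        voi.mask[:] = rng.random((20, 18, 6)) < 0.3
        p = save_roi(voi, tmp_path / "old.roi")
        back = load_roi(p, n_slices=6)
        assert np.array_equal(back.mask, voi.mask)
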