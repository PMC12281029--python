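import gzip
import struct

import numpy as np
import pytest

import nibabel as nib

from voxview import (CorruptFileError, UnsupportedFormatError, Volume,
                     VolumeHeader, read_volume, sniff_format,
                     volume_from_array, write_nifti, write_volume)
from voxview.volio import (affine_to_quaternion, quaternion_to_affine,
                           write_afni, write_mgh, write_nrrd, write_vtk)


def _simple_volume(dtype="float32", shape=(6, 5, 4)):
    rng = np.random.default_rng(7)
    if dtype.startswith("float"):
        data = rng.normal(50, 10, shape).astype(dtype)
    else:
        data = rng.integers(0, 100, shape).astype(dtype)
    return volume_from_array(data, voxel_size=(1.0, 1.5, 2.0), datatype=dtype)


class TestSniff:
    def test_gzip_wrapped_nifti(self, tmp_path):
        p = write_nifti(_simple_volume(), tmp_path / "x.nii.gz")
        raw = p.read_bytes()
        assert raw[:2] == b"\x1f\x8b"
        assert sniff_format(raw, str(p)) == "nifti1_gz"

    def test_nifti_magic_at_offset_344(self, tmp_path):
        p = write_nifti(_simple_volume(), tmp_path / "x.nii", gzipped=False)
        raw = p.read_bytes()
        assert raw[344:348] == b"n+1\x00"  # standard magic location
        assert sniff_format(raw, str(p)) == "nifti1"
        # cross-check: an independent reader accepts the same bytes
        assert nib.load(str(p)).shape == (6, 5, 4)

    def test_empty_file_unknown(self):
        assert sniff_format(b"", "anything") == "unknown"

    @pytest.mark.parametrize("writer,expected", [
        (write_mgh, "mgz"), (write_nrrd, "nrrd"), (write_vtk, "vtk_legacy")])
    def test_other_formats(self, tmp_path, writer, expected):
        name = {"mgz": "x.mgz", "nrrd": "x.nrrd", "vtk_legacy": "x.vtk"}[expected]
        p = writer(_simple_volume(), tmp_path / name)
        assert sniff_format(p.read_bytes()[:4096], str(p)) == expected

    def test_afni_head_text(self, tmp_path):
        p = write_afni(_simple_volume(), tmp_path / "x+orig.HEAD")
        assert sniff_format(p.read_bytes(), str(p)) == "afni"

    def test_unknown_format_raises_on_read(self, tmp_path):
        p = tmp_path / "junk.bin"
        p.write_bytes(b"\x00" * 400)
        with pytest.raises(UnsupportedFormatError):
            read_volume(p)


class TestNifti:
    def test_slope_intercept_applied(self, tmp_path):
        # stored int16 value 5 with slope 2, inter 10 -> in-memory 20.0
        data = np.full((3, 3, 3), 5, dtype=np.int16)
        hdr = VolumeHeader(dims=(3, 3, 3), voxel_size=(1, 1, 1), datatype="int16",
                           scl_slope=2.0, scl_inter=10.0,
                           sform_code=1, sform=np.eye(4))
        vol = Volume(header=hdr, data=data.astype(np.float64) * 2 + 10)
        p = write_nifti(vol, tmp_path / "s.nii", gzipped=False)
        back = read_volume(p)
        assert float(back.data[0, 0, 0]) == 20.0
        # independent reader agrees on the scaled value
        assert float(np.asarray(nib.load(str(p)).dataobj)[0, 0, 0]) == 20.0

    def test_uint8_roundtrip_bit_exact(self, tmp_path):
        vol = _simple_volume("uint8")
        p = write_nifti(vol, tmp_path / "u.nii.gz")
        back = read_volume(p)
        assert back.data.dtype == np.uint8
        assert np.array_equal(back.data, vol.data)

    def test_qform_roundtrip(self, tmp_path):
        # a rotated affine, written and re-read through the qform only
        theta = 0.3
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        aff = np.eye(4)
        aff[:3, :3] = rot @ np.diag([1.0, 1.2, 2.0])
        aff[:3, 3] = (-10.0, 5.0, 2.5)
        vol = volume_from_array(np.zeros((4, 4, 4), dtype=np.float32), affine=aff)
        p = write_nifti(vol, tmp_path / "q.nii", gzipped=False)
        raw = bytearray(p.read_bytes())
        struct.pack_into("<h", raw, 254, 0)  # zero the sform code: force qform path
        p.write_bytes(bytes(raw))
        back = read_volume(p)
        assert np.max(np.abs(back.affine - aff)) < 1e-5

    def test_quaternion_encode_decode_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            a, b, c, d = q if q[0] >= 0 else -q
            R = np.array([
                [a*a+b*b-c*c-d*d, 2*(b*c-a*d), 2*(b*d+a*c)],
                [2*(b*c+a*d), a*a+c*c-b*b-d*d, 2*(c*d-a*b)],
                [2*(b*d-a*c), 2*(c*d+a*b), a*a+d*d-b*b-c*c]])
            aff = np.eye(4)
            aff[:3, :3] = R * np.array([1.0, 1.5, 2.0])
            bb, cc, dd, qfac, pix = affine_to_quaternion(aff)
            back = quaternion_to_affine(bb, cc, dd, qfac, pix, np.zeros(3))
            assert np.max(np.abs(back - aff)) < 1e-9

    def test_truncated_data_reports_byte_counts(self, tmp_path):
        p = write_nifti(_simple_volume(), tmp_path / "t.nii", gzipped=False)
        raw = p.read_bytes()
        p.write_bytes(raw[:len(raw) - 40])
        with pytest.raises(CorruptFileError, match=r"expected \d+ bytes"):
            read_volume(p)

    def test_4d_truncated_to_first_volume(self, tmp_path, caplog):
        vol = _simple_volume()
        p = write_nifti(vol, tmp_path / "v4.nii", gzipped=False)
        raw = bytearray(p.read_bytes())
        struct.pack_into("<8h", raw, 40, 4, 6, 5, 4, 3, 1, 1, 1)  # claim 3 volumes
        extra = bytes(raw[352:]) * 2
        p.write_bytes(bytes(raw) + extra)
        back = read_volume(p)
        assert back.shape == (6, 5, 4)
        assert np.allclose(back.data, vol.data, atol=1e-6)


class TestCrossFormat:
    def test_big_endian_mgh_equals_little_endian_nifti(self, tmp_path, phantom):
        p_nii = write_nifti(phantom, tmp_path / "p.nii.gz")
        p_mgh = write_mgh(phantom, tmp_path / "p.mgh")
        a = read_volume(p_nii)
        b = read_volume(p_mgh)
        assert a.header.endianness == "little"
        assert b.header.endianness == "big"
        assert np.array_equal(a.data, b.data)
        assert np.max(np.abs(a.affine - b.affine)) < 1e-3

    def test_mgh_agrees_with_independent_reader(self, tmp_path, phantom):
        p = write_mgh(phantom, tmp_path / "p.mgz")
        mine = read_volume(p)
        theirs = nib.load(str(p))
        assert np.array_equal(np.asarray(theirs.dataobj, dtype=np.float32),
                              np.asarray(mine.data, dtype=np.float32))
        assert np.max(np.abs(theirs.affine - mine.affine)) < 1e-4

    def test_afni_agrees_with_independent_reader(self, tmp_path, phantom):
        p = write_afni(phantom, tmp_path / "p+orig.HEAD")
        mine = read_volume(p)
        theirs = nib.load(str(p))
        assert np.allclose(np.asarray(theirs.dataobj).squeeze(), mine.data,
                           atol=1e-5)
        assert np.max(np.abs(theirs.affine - mine.affine)) < 1e-4

    def test_nrrd_raw_and_gzip_encodings_match(self, tmp_path, phantom):
        a = read_volume(write_nrrd(phantom, tmp_path / "a.nrrd", encoding="raw"))
        b = read_volume(write_nrrd(phantom, tmp_path / "b.nrrd", encoding="gzip"))
        assert np.array_equal(a.data, b.data)

    def test_vtk_ascii_read(self, tmp_path):
        data = np.arange(24, dtype=np.float32).reshape(2, 3, 4)
        body = " ".join(str(float(x)) for x in data.ravel(order="F"))
        text = ("# vtk DataFile Version 3.0\nvol\nASCII\n"
                "DATASET STRUCTURED_POINTS\nDIMENSIONS 2 3 4\n"
                "SPACING 1.0 1.0 1.0\nORIGIN 0.0 0.0 0.0\n"
                "POINT_DATA 24\nSCALARS s float 1\nLOOKUP_TABLE default\n" + body)
        p = tmp_path / "a.vtk"
        p.write_text(text)
        vol = read_volume(p)
        assert np.array_equal(vol.data, data)

    def test_writer_rejects_rotated_affine_for_diagonal_formats(self, tmp_path):
        aff = np.eye(4)
        aff[:3, :3] = np.array([[0.8, -0.6, 0], [0.6, 0.8, 0], [0, 0, 1.0]])
        vol = volume_from_array(np.zeros((4, 4, 4), dtype=np.float32), affine=aff)
        from voxview.errors import ValidationError
        with pytest.raises(ValidationError):
            write_vtk(vol, tmp_path / "r.vtk")
        with pytest.raises(ValidationError):
            write_afni(vol, tmp_path / "r+orig.HEAD")

    def test_write_volume_dispatch_unknown(self, tmp_path):
        with pytest.raises(UnsupportedFormatError):
            write_volume(_simple_volume(), tmp_path / "x.foo", "foo")
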