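"""Volumetric file I/O with magic-byte format sniffing.

Supported formats: NIfTI-1 (.nii / .nii.gz), FreeSurfer MGH/MGZ, AFNI
HEAD/BRIK, NRRD (attached data, raw or gzip encoding), and legacy VTK
STRUCTURED_POINTS.  All readers produce the same in-memory ``Volume``:
a 3D array (slope/intercept already applied) plus a header carrying the
voxel->world affine in RAS+ millimetres, mapping the *center* of voxel
(i, j, k) to world space with 0-based indices.

Voxel data are stored i-fastest on disk in every supported format, so
arrays here are indexed ``data[i, j, k]`` and serialized in Fortran order.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CorruptFileError, UnsupportedFormatError, ValidationError

log = logging.getLogger(__name__)

# on-disk datatype name -> (NIfTI code, bits, numpy dtype)
_NIFTI_DTYPES = {
    "uint8": (2, 8, np.uint8),
    "int16": (4, 16, np.int16),
    "int32": (8, 32, np.int32),
    "float32": (16, 32, np.float32),
    "float64": (64, 64, np.float64),
}
_NIFTI_CODE_TO_NAME = {code: name for name, (code, _, _) in _NIFTI_DTYPES.items()}

_MGH_TYPES = {"uint8": 0, "int32": 1, "float32": 3, "int16": 4}
_MGH_CODE_TO_NAME = {v: k for k, v in _MGH_TYPES.items()}

_NRRD_TYPES = {
    "uchar": "uint8", "unsigned char": "uint8", "uint8": "uint8",
    "short": "int16", "int16": "int16", "signed short": "int16",
    "int": "int32", "int32": "int32",
    "float": "float32", "double": "float64",
}
_NRRD_NAME = {"uint8": "uchar", "int16": "short", "int32": "int",
              "float32": "float", "float64": "double"}

_VTK_TYPES = {"unsigned_char": "uint8", "short": "int16", "int": "int32",
              "float": "float32", "double": "float64"}
_VTK_NAME = {v: k for k, v in _VTK_TYPES.items()}

_AFNI_BRICK_TYPES = {0: "uint8", 1: "int16", 3: "float32"}
_AFNI_TYPE_CODE = {"uint8": 0, "int16": 1, "float32": 3}


@dataclass
class VolumeHeader:
    """Geometry and storage metadata for a :class:`Volume`."""

    dims: tuple[int, ...]
    voxel_size: tuple[float, float, float]
    datatype: str = "float32"
    scl_slope: float = 1.0
    scl_inter: float = 0.0
    qform_code: int = 0
    sform_code: int = 1
    qform: np.ndarray | None = None
    sform: np.ndarray | None = None
    endianness: str = "little"
    description: str = ""

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValidationError(f"dims must be positive, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.datatype not in _NIFTI_DTYPES:
            raise ValidationError(f"unsupported datatype {self.datatype!r}")

    @property
    def affine(self) -> np.ndarray:
        """Voxel->world affine: sform if valid, else qform, else pixdim diagonal."""
        if self.sform_code > 0 and self.sform is not None:
            return np.asarray(self.sform, dtype=float)
        if self.qform_code > 0 and self.qform is not None:
            return np.asarray(self.qform, dtype=float)
        log.warning("no qform/sform; falling back to diagonal voxel scaling")
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


@dataclass
class Volume:
    """A 3D image: scaled voxel data plus header."""

    header: VolumeHeader
    data: np.ndarray
    source_format: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.header.dims[:3]):
            raise ValidationError(
                f"data shape {self.data.shape} != header dims {self.header.dims[:3]}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValidationError("volume data contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        return self.header.affine

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.header.voxel_size


def volume_from_array(
    data: np.ndarray,
    affine: np.ndarray | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    datatype: str | None = None,
    description: str = "",
    source_format: str = "synthetic",
) -> Volume:
    """Wrap an array as a Volume; affine defaults to diag(voxel_size)."""
    data = np.asarray(data)
    if affine is None:
        vs = voxel_size or (1.0, 1.0, 1.0)
        affine = np.diag((*vs, 1.0)).astype(float)
    affine = np.asarray(affine, dtype=float)
    if voxel_size is None:
        voxel_size = tuple(np.linalg.norm(affine[:3, :3], axis=0))
    if datatype is None:
        datatype = data.dtype.name if data.dtype.name in _NIFTI_DTYPES else "float32"
    hdr = VolumeHeader(
        dims=tuple(int(d) for d in data.shape),
        voxel_size=tuple(float(v) for v in voxel_size),
        datatype=datatype,
        sform_code=1, sform=affine,
        qform_code=1, qform=affine,
        description=description,
    )
    return Volume(header=hdr, data=data, source_format=source_format)


# ---------------------------------------------------------------------------
# format sniffing

def _looks_like_nifti(raw: bytes) -> bool:
    if len(raw) < 348:
        return False
    return raw[344:348] in (b"n+1\x00", b"ni1\x00")


def _looks_like_mgh(raw: bytes) -> bool:
    if len(raw) < 20:
        return False
    version, w, h, d = struct.unpack(">4i", raw[:16])
    dtype_code = struct.unpack(">i", raw[16:20])[0]
    return (version == 1 and all(0 < x < 2 ** 20 for x in (w, h, d))
            and dtype_code in _MGH_CODE_TO_NAME)


def _looks_like_afni_head(raw: bytes) -> bool:
    try:
        text = raw.decode("ascii", errors="strict")
    except UnicodeDecodeError:
        return False
    return "name = DATASET_RANK" in text or (
        "-attribute" in text and "name =" in text)


def sniff_format(first_bytes: bytes, path_hint: str = "") -> str:
    """Identify a volume format from leading bytes.

    Returns one of ``nifti1, nifti1_gz, mgh, mgz, afni, nrrd, vtk_legacy,
    unknown``.  ``path_hint`` breaks the tie between ``.mgz`` and ``.nii.gz``
    only when the decompressed content is ambiguous.
    """
    raw = bytes(first_bytes)
    if raw[:2] == b"\x1f\x8b":
        try:
            inner = gzip.decompress(raw) if len(raw) < 10 ** 6 else b""
        except (OSError, EOFError):
            # partial gzip stream: decompress what we can
            try:
                inner = gzip.GzipFile(fileobj=io.BytesIO(raw)).read(512)
            except (OSError, EOFError):
                inner = b""
        if _looks_like_nifti(inner):
            return "nifti1_gz"
        if _looks_like_mgh(inner):
            return "mgz"
        hint = path_hint.lower()
        if hint.endswith(".mgz"):
            return "mgz"
        if hint.endswith(".nii.gz") or hint.endswith(".voi"):
            return "nifti1_gz"
        return "unknown"
    if _looks_like_nifti(raw):
        return "nifti1"
    if raw[:7] == b"NRRD000":
        return "nrrd"
    if raw[:14] == b"# vtk DataFile":
        return "vtk_legacy"
    if _looks_like_afni_head(raw):
        return "afni"
    if _looks_like_mgh(raw):
        return "mgh"
    return "unknown"


# ---------------------------------------------------------------------------
# NIfTI-1

def _quaternion_to_rotation(b: float, c: float, d: float) -> np.ndarray:
    a2 = 1.0 - (b * b + c * c + d * d)
    a = np.sqrt(a2) if a2 > 0 else 0.0
    return np.array([
        [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
        [2 * (b * c + a * d), a * a + c * c - b * b - d * d, 2 * (c * d - a * b)],
        [2 * (b * d - a * c), 2 * (c * d + a * b), a * a + d * d - b * b - c * c],
    ])


def _rotation_to_quaternion(R: np.ndarray) -> tuple[float, float, float]:
    tr = np.trace(R)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2
        a = 0.25 * s
        b = (R[2, 1] - R[1, 2]) / s
        c = (R[0, 2] - R[2, 0]) / s
        d = (R[1, 0] - R[0, 1]) / s
    elif R[0, 0] >= R[1, 1] and R[0, 0] >= R[2, 2]:
        s = np.sqrt(1.0 + R[0, 0] - R[1, 1] - R[2, 2]) * 2
        a = (R[2, 1] - R[1, 2]) / s
        b = 0.25 * s
        c = (R[0, 1] + R[1, 0]) / s
        d = (R[0, 2] + R[2, 0]) / s
    elif R[1, 1] >= R[2, 2]:
        s = np.sqrt(1.0 + R[1, 1] - R[0, 0] - R[2, 2]) * 2
        a = (R[0, 2] - R[2, 0]) / s
        b = (R[0, 1] + R[1, 0]) / s
        c = 0.25 * s
        d = (R[1, 2] + R[2, 1]) / s
    else:
        s = np.sqrt(1.0 + R[2, 2] - R[0, 0] - R[1, 1]) * 2
        a = (R[1, 0] - R[0, 1]) / s
        b = (R[0, 2] + R[2, 0]) / s
        c = (R[1, 2] + R[2, 1]) / s
        d = 0.25 * s
    if a < 0:
        b, c, d = -b, -c, -d
    return float(b), float(c), float(d)


def affine_to_quaternion(affine: np.ndarray) -> tuple[float, float, float, float, np.ndarray]:
    """Decompose a voxel->world affine into (b, c, d, qfac, pixdim)."""
    A = np.asarray(affine, dtype=float)
    pixdim = np.linalg.norm(A[:3, :3], axis=0)
    if np.any(pixdim == 0):
        raise ValidationError("affine has a zero-length column")
    R = A[:3, :3] / pixdim
    qfac = 1.0
    if np.linalg.det(R) < 0:
        qfac = -1.0
        R = R.copy()
        R[:, 2] *= -1
    # snap to the nearest rotation so shear/roundoff cannot break the encode
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    b, c, d = _rotation_to_quaternion(R)
    return b, c, d, qfac, pixdim


def quaternion_to_affine(b, c, d, qfac, pixdim, offset) -> np.ndarray:
    R = _quaternion_to_rotation(b, c, d)
    aff = np.eye(4)
    aff[:3, :3] = R * np.asarray(pixdim, dtype=float)
    aff[:3, 2] *= 1.0 if qfac >= 0 else -1.0
    aff[:3, 3] = offset
    return aff


def _pack_nifti_header(vol: Volume) -> bytes:
    hdr = vol.header
    code, bitpix, _ = _NIFTI_DTYPES[hdr.datatype]
    dim = [3, *vol.shape, 1, 1, 1, 1]
    affine = vol.affine
    b, c, d, qfac, pixdim3 = affine_to_quaternion(affine)
    pixdim = [qfac, *pixdim3, 0.0, 0.0, 0.0, 0.0]
    descrip = hdr.description.encode("ascii", errors="replace")[:79]

    buf = bytearray(348)
    struct.pack_into("<i", buf, 0, 348)
    buf[38] = ord("r")  # regular
    struct.pack_into("<8h", buf, 40, *dim)
    struct.pack_into("<h", buf, 70, code)
    struct.pack_into("<h", buf, 72, bitpix)
    struct.pack_into("<8f", buf, 76, *pixdim)
    struct.pack_into("<f", buf, 108, 352.0)  # vox_offset
    struct.pack_into("<ff", buf, 112, hdr.scl_slope, hdr.scl_inter)
    buf[123] = 2  # xyzt_units: millimetres
    buf[148:148 + len(descrip)] = descrip
    struct.pack_into("<hh", buf, 252, 1, 1)  # qform_code, sform_code
    struct.pack_into("<3f", buf, 256, b, c, d)
    struct.pack_into("<3f", buf, 268, *affine[:3, 3])
    struct.pack_into("<4f", buf, 280, *affine[0])
    struct.pack_into("<4f", buf, 296, *affine[1])
    struct.pack_into("<4f", buf, 312, *affine[2])
    buf[344:348] = b"n+1\x00"
    return bytes(buf) + b"\x00\x00\x00\x00"  # no extensions


def write_nifti(vol: Volume, path: str | Path, gzipped: bool | None = None) -> Path:
    """Write a single-file NIfTI-1 (.nii or .nii.gz / .voi).

    Both sform and qform are written equal to the volume's affine.  Data are
    cast to the header datatype; integer datatypes are rounded and clipped to
    the representable range, undoing scl_slope/scl_inter where set.
    """
    path = Path(path)
    if gzipped is None:
        gzipped = path.name.endswith(".gz") or path.suffix == ".voi"
    hdr = vol.header
    _, _, np_dtype = _NIFTI_DTYPES[hdr.datatype]
    raw = np.asarray(vol.data, dtype=np.float64)
    slope = hdr.scl_slope if hdr.scl_slope not in (0.0, 0) else 1.0
    if slope != 1.0 or hdr.scl_inter != 0.0:
        raw = (raw - hdr.scl_inter) / slope
    if np.issubdtype(np_dtype, np.integer):
        info = np.iinfo(np_dtype)
        raw = np.clip(np.round(raw), info.min, info.max)
    stored = raw.astype(np_dtype)
    payload = _pack_nifti_header(vol) + stored.ravel(order="F").tobytes()
    if gzipped:
        with gzip.GzipFile(path, "wb", mtime=0) as fh:  # mtime=0: stable bytes
            fh.write(payload)
    else:
        path.write_bytes(payload)
    return path


def _read_nifti_bytes(raw: bytes) -> Volume:
    if len(raw) < 352:
        raise CorruptFileError(f"NIfTI stream too short: {len(raw)} bytes < 352")
    for endian in ("<", ">"):
        if struct.unpack_from(endian + "i", raw, 0)[0] == 348:
            break
    else:
        raise CorruptFileError("NIfTI sizeof_hdr != 348 under either byte order")
    dim = struct.unpack_from(endian + "8h", raw, 40)
    ndim = dim[0]
    shape4 = tuple(int(x) for x in dim[1:1 + max(ndim, 3)])
    code = struct.unpack_from(endian + "h", raw, 70)[0]
    if code not in _NIFTI_CODE_TO_NAME:
        raise UnsupportedFormatError(f"NIfTI datatype code {code} not supported")
    dtype_name = _NIFTI_CODE_TO_NAME[code]
    pixdim = struct.unpack_from(endian + "8f", raw, 76)
    vox_offset = int(struct.unpack_from(endian + "f", raw, 108)[0])
    scl_slope, scl_inter = struct.unpack_from(endian + "ff", raw, 112)
    descrip = raw[148:228].split(b"\x00")[0].decode("ascii", errors="replace")
    qform_code, sform_code = struct.unpack_from(endian + "hh", raw, 252)
    qb, qc, qd = struct.unpack_from(endian + "3f", raw, 256)
    qoffset = struct.unpack_from(endian + "3f", raw, 268)
    srow = np.array([struct.unpack_from(endian + "4f", raw, off)
                     for off in (280, 296, 312)])

    shape3 = shape4[:3]
    n_total = int(np.prod(shape4[:max(ndim, 3)]))
    n_vol = int(np.prod(shape3))
    _, _, np_dtype = _NIFTI_DTYPES[dtype_name]
    dt = np.dtype(np_dtype).newbyteorder(endian)
    need = n_vol * dt.itemsize
    avail = len(raw) - vox_offset
    if avail < need:
        raise CorruptFileError(
            f"NIfTI data truncated: expected {need} bytes, found {avail}")
    if ndim > 3 and n_total > n_vol:
        log.warning("4D NIfTI input: loading first volume only (%d present)",
                    n_total // n_vol)
    data = np.frombuffer(raw, dtype=dt, count=n_vol, offset=vox_offset)
    data = data.reshape(shape3, order="F").copy()

    qfac = -1.0 if pixdim[0] < 0 else 1.0
    qform = quaternion_to_affine(qb, qc, qd, qfac, pixdim[1:4], qoffset)
    sform = np.vstack([srow, [0, 0, 0, 1]]).astype(float)
    slope = scl_slope if scl_slope not in (0.0,) else 1.0
    scaled: np.ndarray = data
    if slope != 1.0 or scl_inter != 0.0:
        scaled = data.astype(np.float64) * slope + scl_inter
        if dtype_name != "float64":
            scaled = scaled.astype(np.float32)
    if np.issubdtype(scaled.dtype, np.floating) and not np.isfinite(scaled).all():
        raise CorruptFileError("NIfTI data contains NaN/Inf after scaling")
    hdr = VolumeHeader(
        dims=shape3, voxel_size=tuple(abs(float(p)) for p in pixdim[1:4]),
        datatype=dtype_name, scl_slope=float(slope), scl_inter=float(scl_inter),
        qform_code=int(qform_code), sform_code=int(sform_code),
        qform=qform, sform=sform,
        endianness="little" if endian == "<" else "big",
        description=descrip,
    )
    return Volume(header=hdr, data=scaled, source_format="nifti1")


# ---------------------------------------------------------------------------
# FreeSurfer MGH / MGZ

def write_mgh(vol: Volume, path: str | Path, gzipped: bool | None = None) -> Path:
    """Write an MGH (or gzipped MGZ) volume.  MGH is always big-endian."""
    path = Path(path)
    if gzipped is None:
        gzipped = path.suffix == ".mgz" or path.name.endswith(".gz")
    dtype_name = vol.header.datatype
    if dtype_name not in _MGH_TYPES:
        dtype_name = "float32"
    affine = vol.affine
    shape = np.asarray(vol.shape, dtype=float)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    Mdc = affine[:3, :3] / spacing
    center_vox = shape / 2.0
    Pxyz_c = affine[:3, :3] @ center_vox + affine[:3, 3]

    buf = bytearray(284)
    struct.pack_into(">i", buf, 0, 1)  # version
    struct.pack_into(">4i", buf, 4, *vol.shape, 1)
    struct.pack_into(">i", buf, 20, _MGH_TYPES[dtype_name])
    struct.pack_into(">i", buf, 24, 0)  # dof
    struct.pack_into(">h", buf, 28, 1)  # goodRASFlag
    struct.pack_into(">3f", buf, 30, *spacing)
    struct.pack_into(">9f", buf, 42, *Mdc.ravel(order="F"))  # x_r..z_s, column-major
    struct.pack_into(">3f", buf, 78, *Pxyz_c)

    _, _, np_dtype = _NIFTI_DTYPES[dtype_name]
    raw = np.asarray(vol.data, dtype=np.float64)
    if np.issubdtype(np_dtype, np.integer):
        info = np.iinfo(np_dtype)
        raw = np.clip(np.round(raw), info.min, info.max)
    stored = raw.astype(np.dtype(np_dtype).newbyteorder(">"))
    payload = bytes(buf) + stored.ravel(order="F").tobytes()
    if gzipped:
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(payload)
    else:
        path.write_bytes(payload)
    return path


def _read_mgh_bytes(raw: bytes) -> Volume:
    if len(raw) < 284:
        raise CorruptFileError(f"MGH stream too short: {len(raw)} bytes < 284")
    version, w, h, d, nframes = struct.unpack_from(">5i", raw, 0)
    if version != 1:
        raise CorruptFileError(f"MGH version {version} != 1")
    type_code = struct.unpack_from(">i", raw, 20)[0]
    if type_code not in _MGH_CODE_TO_NAME:
        raise UnsupportedFormatError(f"MGH type code {type_code} not supported")
    dtype_name = _MGH_CODE_TO_NAME[type_code]
    good_ras = struct.unpack_from(">h", raw, 28)[0]
    if good_ras > 0:
        spacing = np.array(struct.unpack_from(">3f", raw, 30), dtype=float)
        Mdc = np.array(struct.unpack_from(">9f", raw, 42), dtype=float).reshape(3, 3, order="F")
        Pxyz_c = np.array(struct.unpack_from(">3f", raw, 78), dtype=float)
    else:
        spacing = np.ones(3)
        Mdc = np.diag([-1.0, 1.0, 1.0])  # FreeSurfer default LIA-ish fallback
        Pxyz_c = np.zeros(3)
        log.warning("MGH goodRASFlag<=0: using default direction cosines")
    M = Mdc * spacing
    center_vox = np.array([w, h, d], dtype=float) / 2.0
    t = Pxyz_c - M @ center_vox
    affine = np.eye(4)
    affine[:3, :3] = M
    affine[:3, 3] = t

    if nframes > 1:
        log.warning("multi-frame MGH input: loading first frame only (%d present)", nframes)
    _, _, np_dtype = _NIFTI_DTYPES[dtype_name]
    dt = np.dtype(np_dtype).newbyteorder(">")
    n_vol = w * h * d
    need = n_vol * dt.itemsize
    avail = len(raw) - 284
    if avail < need:
        raise CorruptFileError(f"MGH data truncated: expected {need} bytes, found {avail}")
    data = np.frombuffer(raw, dtype=dt, count=n_vol, offset=284)
    data = data.reshape((w, h, d), order="F").astype(np_dtype)
    hdr = VolumeHeader(
        dims=(w, h, d), voxel_size=tuple(float(s) for s in spacing),
        datatype=dtype_name, sform_code=1, sform=affine, qform_code=1, qform=affine,
        endianness="big",
    )
    return Volume(header=hdr, data=data, source_format="mgh")


# ---------------------------------------------------------------------------
# AFNI HEAD / BRIK

def _parse_afni_head(text: str) -> dict[str, object]:
    attrs: dict[str, object] = {}
    pattern = re.compile(
        r"type\s*=\s*(\S+)\s*name\s*=\s*(\S+)\s*count\s*=\s*(\d+)\s*", re.S)
    pos = 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            break
        kind, name, count = m.group(1), m.group(2), int(m.group(3))
        start = m.end()
        if kind.startswith("string"):
            q = text.index("'", start)
            value: object = text[q + 1: q + count].rstrip("~")
            pos = q + count
        else:
            tokens: list[str] = []
            p = start
            while len(tokens) < count:
                nl = text.find("\n", p)
                chunk = text[p:nl if nl != -1 else len(text)]
                tokens.extend(chunk.split())
                p = (nl + 1) if nl != -1 else len(text)
            conv = int if kind.startswith("integer") else float
            value = [conv(t) for t in tokens[:count]]
            pos = p
        attrs[name] = value
    return attrs


# AFNI orientation codes: per dataset axis, which anatomical axis it runs
# along (in AFNI's DICOM-ordered frame: +x Left, +y Posterior, +z Superior)
# and in which direction.
_AFNI_ORIENT = {0: (0, +1), 1: (0, -1), 2: (1, -1), 3: (1, +1), 4: (2, +1), 5: (2, -1)}
_AFNI_FLIP_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])


def _read_afni(head_path: Path) -> Volume:
    attrs = _parse_afni_head(head_path.read_text())
    try:
        rank = attrs["DATASET_RANK"]
        dims = [int(x) for x in attrs["DATASET_DIMENSIONS"][:3]]  # type: ignore[index]
        orient = [int(x) for x in attrs["ORIENT_SPECIFIC"]]  # type: ignore[index]
        origin = [float(x) for x in attrs["ORIGIN"]]  # type: ignore[index]
        delta = [float(x) for x in attrs["DELTA"]]  # type: ignore[index]
        brick_types = [int(x) for x in attrs["BRICK_TYPES"]]  # type: ignore[index]
    except KeyError as exc:
        raise CorruptFileError(f"AFNI HEAD missing attribute {exc}") from exc
    n_sub = int(rank[1]) if isinstance(rank, list) and len(rank) > 1 else 1  # type: ignore[arg-type]
    facs = attrs.get("BRICK_FLOAT_FACS", [0.0] * n_sub)
    byteorder = str(attrs.get("BYTEORDER_STRING", "LSB_FIRST"))
    endian = ">" if byteorder.startswith("MSB") else "<"

    if brick_types[0] not in _AFNI_BRICK_TYPES:
        raise UnsupportedFormatError(f"AFNI brick type {brick_types[0]} not supported")
    dtype_name = _AFNI_BRICK_TYPES[brick_types[0]]
    _, _, np_dtype = _NIFTI_DTYPES[dtype_name]
    dt = np.dtype(np_dtype).newbyteorder(endian)

    brik = None
    for suffix in (".BRIK", ".BRIK.gz"):
        cand = head_path.with_name(head_path.name[:-len(".HEAD")] + suffix)
        if cand.exists():
            brik = cand
            break
    if brik is None:
        raise CorruptFileError(f"no BRIK file next to {head_path}")
    raw = (gzip.decompress(brik.read_bytes()) if brik.suffix == ".gz"
           else brik.read_bytes())
    n_vol = int(np.prod(dims))
    if len(raw) < n_vol * dt.itemsize:
        raise CorruptFileError(
            f"AFNI BRIK truncated: expected {n_vol * dt.itemsize} bytes, found {len(raw)}")
    if n_sub > 1:
        log.warning("AFNI dataset has %d sub-bricks: loading sub-brick 0 only", n_sub)
    data = np.frombuffer(raw, dtype=dt, count=n_vol).reshape(dims, order="F")
    data = data.astype(np_dtype)
    fac = float(facs[0]) if facs else 0.0  # type: ignore[index]
    scaled: np.ndarray = data
    if fac not in (0.0,):
        scaled = data.astype(np.float32) * fac

    # affine in AFNI's frame, then negate x/y rows for RAS
    A = np.eye(4)
    for i, code in enumerate(orient):
        axis, _ = _AFNI_ORIENT[code]
        A[axis, i] = delta[i]
        A[axis, 3] = origin[i]
    affine = _AFNI_FLIP_TO_RAS @ A
    hdr = VolumeHeader(
        dims=tuple(dims), voxel_size=tuple(abs(d) for d in delta),
        datatype=dtype_name, sform_code=1, sform=affine, qform_code=1, qform=affine,
        endianness="little" if endian == "<" else "big",
    )
    return Volume(header=hdr, data=scaled, source_format="afni")


def _afni_attr(kind: str, name: str, value) -> str:
    lines = [f"type = {kind}-attribute", f"name = {name}"]
    if kind == "string":
        payload = value + "~"
        lines.append(f"count = {len(payload)}")
        lines.append(f"'{payload}")
    else:
        vals = list(value)
        lines.append(f"count = {len(vals)}")
        fmt = (lambda v: str(int(v))) if kind == "integer" else (lambda v: repr(float(v)))
        lines.append("  " + " ".join(fmt(v) for v in vals))
    return "\n".join(lines) + "\n\n"


def write_afni(vol: Volume, head_path: str | Path) -> Path:
    """Write an AFNI HEAD/BRIK pair.  Requires a near-axis-aligned affine."""
    head_path = Path(head_path)
    if not head_path.name.endswith(".HEAD"):
        head_path = head_path.with_suffix(".HEAD")
    affine = vol.affine
    A = _AFNI_FLIP_TO_RAS @ affine  # into AFNI's DICOM-ordered frame
    orient, delta, origin = [], [], []
    seen = set()
    for i in range(3):
        col = A[:3, i]
        axis = int(np.argmax(np.abs(col)))
        if axis in seen or abs(col[axis]) < 1e-9 or (
                np.linalg.norm(col) - abs(col[axis])) > 1e-6 * np.linalg.norm(col):
            raise ValidationError("AFNI writer requires an axis-aligned affine")
        seen.add(axis)
        sign = 1 if col[axis] > 0 else -1
        code = {(0, 1): 0, (0, -1): 1, (1, -1): 2, (1, 1): 3, (2, 1): 4, (2, -1): 5}[(axis, sign)]
        orient.append(code)
        delta.append(float(col[axis]))
        origin.append(float(A[axis, 3]))

    dtype_name = vol.header.datatype
    if dtype_name not in _AFNI_TYPE_CODE:
        dtype_name = "float32"
    _, _, np_dtype = _NIFTI_DTYPES[dtype_name]
    raw = np.asarray(vol.data, dtype=np.float64)
    if np.issubdtype(np_dtype, np.integer):
        info = np.iinfo(np_dtype)
        raw = np.clip(np.round(raw), info.min, info.max)
    stored = raw.astype(np_dtype)

    head = "".join([
        _afni_attr("integer", "DATASET_RANK", [3, 1, 0, 0, 0, 0, 0, 0]),
        _afni_attr("integer", "DATASET_DIMENSIONS", [*vol.shape, 0, 0]),
        _afni_attr("integer", "ORIENT_SPECIFIC", orient),
        _afni_attr("float", "ORIGIN", origin),
        _afni_attr("float", "DELTA", delta),
        _afni_attr("integer", "BRICK_TYPES", [_AFNI_TYPE_CODE[dtype_name]]),
        _afni_attr("float", "IJK_TO_DICOM_REAL", list(A[:3].ravel())),
        _afni_attr("float", "BRICK_FLOAT_FACS", [0.0]),
        _afni_attr("string", "BYTEORDER_STRING", "LSB_FIRST"),
        _afni_attr("integer", "SCENE_DATA", [0, 11, 1, -999, -999, -999, -999, -999]),
    ]).rstrip("\n") + "\n"
    head_path.write_text(head)
    brik_path = head_path.with_name(head_path.name[:-len(".HEAD")] + ".BRIK")
    brik_path.write_bytes(stored.ravel(order="F").tobytes())
    return head_path


# ---------------------------------------------------------------------------
# NRRD (attached data only)

def write_nrrd(vol: Volume, path: str | Path, encoding: str = "gzip") -> Path:
    path = Path(path)
    if encoding not in ("raw", "gzip"):
        raise ValidationError(f"NRRD encoding must be raw or gzip, got {encoding!r}")
    affine = vol.affine
    dirs = " ".join("(" + ",".join(repr(float(x)) for x in affine[:3, i]) + ")"
                    for i in range(3))
    origin = "(" + ",".join(repr(float(x)) for x in affine[:3, 3]) + ")"
    _, _, np_dtype = _NIFTI_DTYPES[vol.header.datatype]
    raw = np.asarray(vol.data, dtype=np.float64)
    if np.issubdtype(np_dtype, np.integer):
        info = np.iinfo(np_dtype)
        raw = np.clip(np.round(raw), info.min, info.max)
    stored = raw.astype(np_dtype)
    header = (
        "NRRD0004\n"
        "# Complete NRRD file format specification at http://teem.sourceforge.net/nrrd/format.html\n"
        f"type: {_NRRD_NAME[vol.header.datatype]}\n"
        "dimension: 3\n"
        "space: right-anterior-superior\n"
        f"sizes: {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}\n"
        f"space directions: {dirs}\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        f"encoding: {encoding}\n"
        f"space origin: {origin}\n"
        "\n"
    )
    body = stored.ravel(order="F").tobytes()
    if encoding == "gzip":
        body = gzip.compress(body, mtime=0)
    path.write_bytes(header.encode("ascii") + body)
    return path


_NRRD_VEC = re.compile(r"\(([^)]*)\)")


def _read_nrrd_bytes(raw: bytes) -> Volume:
    nl = raw.find(b"\n\n")
    if nl == -1:
        raise CorruptFileError("NRRD header not terminated by blank line")
    header_text = raw[:nl].decode("ascii", errors="replace")
    fields: dict[str, str] = {}
    for line in header_text.splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip()
    if "data file" in fields or "datafile" in fields:
        raise UnsupportedFormatError("detached-data NRRD files are not supported")
    if int(fields.get("dimension", "0")) != 3:
        raise UnsupportedFormatError("only 3D scalar NRRD volumes are supported")
    type_name = _NRRD_TYPES.get(fields.get("type", ""))
    if type_name is None:
        raise UnsupportedFormatError(f"NRRD type {fields.get('type')!r} not supported")
    encoding = fields.get("encoding", "raw")
    if encoding not in ("raw", "gzip", "gz"):
        raise UnsupportedFormatError(f"NRRD encoding {encoding!r} not supported")
    sizes = [int(x) for x in fields["sizes"].split()]
    endian = ">" if fields.get("endian", "little").startswith("big") else "<"

    affine = np.eye(4)
    if "space directions" in fields:
        vecs = _NRRD_VEC.findall(fields["space directions"])
        for i, vec in enumerate(vecs[:3]):
            affine[:3, i] = [float(x) for x in vec.split(",")]
    else:
        spacings = fields.get("spacings")
        if spacings:
            affine[:3, :3] = np.diag([float(x) for x in spacings.split()])
    if "space origin" in fields:
        vec = _NRRD_VEC.findall(fields["space origin"])[0]
        affine[:3, 3] = [float(x) for x in vec.split(",")]
    space = fields.get("space", "right-anterior-superior").lower()
    if space in ("left-posterior-superior", "lps"):
        affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine
    elif space in ("left-anterior-superior", "las"):
        affine = np.diag([-1.0, 1.0, 1.0, 1.0]) @ affine

    body = raw[nl + 2:]
    if encoding in ("gzip", "gz"):
        body = gzip.decompress(body)
    _, _, np_dtype = _NIFTI_DTYPES[type_name]
    dt = np.dtype(np_dtype).newbyteorder(endian)
    n_vol = int(np.prod(sizes))
    if len(body) < n_vol * dt.itemsize:
        raise CorruptFileError(
            f"NRRD data truncated: expected {n_vol * dt.itemsize} bytes, found {len(body)}")
    data = np.frombuffer(body, dtype=dt, count=n_vol).reshape(sizes, order="F")
    data = data.astype(np_dtype)
    hdr = VolumeHeader(
        dims=tuple(sizes), voxel_size=tuple(np.linalg.norm(affine[:3, :3], axis=0)),
        datatype=type_name, sform_code=1, sform=affine, qform_code=1, qform=affine,
        endianness="little" if endian == "<" else "big",
    )
    return Volume(header=hdr, data=data, source_format="nrrd")


# ---------------------------------------------------------------------------
# legacy VTK STRUCTURED_POINTS

def write_vtk(vol: Volume, path: str | Path) -> Path:
    """Write a legacy-VTK STRUCTURED_POINTS volume (BINARY, big-endian).

    VTK structured points carry only origin + spacing, so the affine must be
    diagonal with positive spacing.
    """
    path = Path(path)
    affine = vol.affine
    off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    if np.any(np.abs(off_diag) > 1e-9) or np.any(np.diag(affine[:3, :3]) <= 0):
        raise ValidationError(
            "VTK structured points require a positive diagonal affine")
    spacing = np.diag(affine[:3, :3])
    origin = affine[:3, 3]
    _, _, np_dtype = _NIFTI_DTYPES[vol.header.datatype]
    raw = np.asarray(vol.data, dtype=np.float64)
    if np.issubdtype(np_dtype, np.integer):
        info = np.iinfo(np_dtype)
        raw = np.clip(np.round(raw), info.min, info.max)
    stored = raw.astype(np.dtype(np_dtype).newbyteorder(">"))  # VTK binary is big-endian
    header = (
        "# vtk DataFile Version 3.0\n"
        "voxview volume\n"
        "BINARY\n"
        "DATASET STRUCTURED_POINTS\n"
        f"DIMENSIONS {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}\n"
        f"SPACING {float(spacing[0])!r} {float(spacing[1])!r} {float(spacing[2])!r}\n"
        f"ORIGIN {float(origin[0])!r} {float(origin[1])!r} {float(origin[2])!r}\n"
        f"POINT_DATA {int(np.prod(vol.shape))}\n"
        f"SCALARS intensity {_VTK_NAME[vol.header.datatype]} 1\n"
        "LOOKUP_TABLE default\n"
    )
    path.write_bytes(header.encode("ascii") + stored.ravel(order="F").tobytes())
    return path


def _read_vtk_bytes(raw: bytes) -> Volume:
    # header is line-oriented ASCII up to LOOKUP_TABLE (binary) or throughout (ascii)
    head_end = raw.find(b"LOOKUP_TABLE")
    if head_end == -1:
        raise CorruptFileError("VTK file has no LOOKUP_TABLE line")
    line_end = raw.find(b"\n", head_end)
    header_text = raw[:line_end].decode("ascii", errors="replace")
    lines = [ln.strip() for ln in header_text.splitlines() if ln.strip()]
    fmt = None
    dims = spacing = origin = None
    scalar_type = None
    n_points = None
    for ln in lines:
        up = ln.upper()
        if up in ("BINARY", "ASCII"):
            fmt = up
        elif up.startswith("DATASET"):
            if "STRUCTURED_POINTS" not in up:
                raise UnsupportedFormatError(
                    f"only STRUCTURED_POINTS VTK datasets are supported, got {ln!r}")
        elif up.startswith("DIMENSIONS"):
            dims = [int(x) for x in ln.split()[1:4]]
        elif up.startswith("SPACING") or up.startswith("ASPECT_RATIO"):
            spacing = [float(x) for x in ln.split()[1:4]]
        elif up.startswith("ORIGIN"):
            origin = [float(x) for x in ln.split()[1:4]]
        elif up.startswith("POINT_DATA"):
            n_points = int(ln.split()[1])
        elif up.startswith("SCALARS"):
            scalar_type = ln.split()[2].lower()
    if fmt is None or dims is None or scalar_type is None:
        raise CorruptFileError("VTK header missing BINARY/ASCII, DIMENSIONS or SCALARS")
    if scalar_type not in _VTK_TYPES:
        raise UnsupportedFormatError(f"VTK scalar type {scalar_type!r} not supported")
    spacing = spacing or [1.0, 1.0, 1.0]
    origin = origin or [0.0, 0.0, 0.0]
    dtype_name = _VTK_TYPES[scalar_type]
    _, _, np_dtype = _NIFTI_DTYPES[dtype_name]
    n_vol = int(np.prod(dims))
    if n_points is not None and n_points != n_vol:
        raise CorruptFileError(f"VTK POINT_DATA {n_points} != DIMENSIONS product {n_vol}")
    body = raw[line_end + 1:]
    if fmt == "BINARY":
        dt = np.dtype(np_dtype).newbyteorder(">")
        if len(body) < n_vol * dt.itemsize:
            raise CorruptFileError(
                f"VTK data truncated: expected {n_vol * dt.itemsize} bytes, found {len(body)}")
        data = np.frombuffer(body, dtype=dt, count=n_vol)
    else:
        tokens = body.split()
        if len(tokens) < n_vol:
            raise CorruptFileError(
                f"VTK ASCII data truncated: expected {n_vol} values, found {len(tokens)}")
        data = np.array([float(t) for t in tokens[:n_vol]])
    data = data.astype(np_dtype).reshape(dims, order="F")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    hdr = VolumeHeader(
        dims=tuple(dims), voxel_size=tuple(spacing), datatype=dtype_name,
        sform_code=1, sform=affine, qform_code=1, qform=affine, endianness="big",
    )
    return Volume(header=hdr, data=data, source_format="vtk_legacy")


# ---------------------------------------------------------------------------
# dispatch

def read_volume(path: str | Path) -> Volume:
    """Read any supported volume format, sniffing the format from its bytes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name
    if name.endswith(".BRIK") or name.endswith(".BRIK.gz"):
        stem = name[:-len(".BRIK.gz")] if name.endswith(".BRIK.gz") else name[:-len(".BRIK")]
        return _read_afni(path.with_name(stem + ".HEAD"))
    raw = path.read_bytes()
    fmt = sniff_format(raw[:4096] if len(raw) > 4096 else raw, str(path))
    if fmt in ("nifti1_gz", "mgz"):
        raw = gzip.decompress(raw)
        fmt = "nifti1" if fmt == "nifti1_gz" else "mgh"
    if fmt == "nifti1":
        vol = _read_nifti_bytes(raw)
    elif fmt == "mgh":
        vol = _read_mgh_bytes(raw)
    elif fmt == "afni":
        vol = _read_afni(path)
    elif fmt == "nrrd":
        vol = _read_nrrd_bytes(raw)
    elif fmt == "vtk_legacy":
        vol = _read_vtk_bytes(raw)
    else:
        raise UnsupportedFormatError(f"cannot identify format of {path}")
    return vol


_WRITERS = {
    "nifti1": lambda vol, p: write_nifti(vol, p, gzipped=False),
    "nifti1_gz": lambda vol, p: write_nifti(vol, p, gzipped=True),
    "mgh": lambda vol, p: write_mgh(vol, p, gzipped=False),
    "mgz": lambda vol, p: write_mgh(vol, p, gzipped=True),
    "afni": write_afni,
    "nrrd": write_nrrd,
    "vtk_legacy": write_vtk,
}


def write_volume(vol: Volume, path: str | Path, fmt: str) -> Path:
    """Write ``vol`` in the named format (see ``_WRITERS`` keys)."""
    if fmt not in _WRITERS:
        raise UnsupportedFormatError(f"no writer for format {fmt!r}")
    return Path(_WRITERS[fmt](vol, path))
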