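"""Volume container and MetaImage / NIfTI input-output.

Coordinate convention (used throughout the package)
---------------------------------------------------
Arrays are indexed ``(slice, row, col)``, 0-based.  ``spacing`` and
``origin`` follow the same axis order and are expressed in millimetres.
The physical position of voxel ``(s, r, c)`` is

    position = origin + index * spacing        (voxel-centre convention)

NIfTI files are written with a diagonal affine so that a write/read
round trip preserves the grid, spacing and origin exactly.  MetaImage
(.mha) support is a minimal uncompressed LOCAL-raw implementation of
the text-header format, sufficient for scalar volumes with spacing and
offset metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

SEQUENCE_LABELS = ("ADC", "HBV", "T2")


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be interpreted."""


@dataclass
class SequenceVolume:
    """One MRI sequence: a 3-D scalar grid plus physical metadata.

    Parameters
    ----------
    data : ndarray, shape (slices, rows, cols)
    spacing : tuple of float
        Voxel size ``(slice, row, col)`` in mm; all components > 0.
    origin : tuple of float
        Physical position (mm) of voxel (0, 0, 0), same axis order.
    label : str
        Sequence name, normally one of ``ADC``, ``HBV``, ``T2``.
    valid_box : tuple or None
        ``(r0, r1, c0, c1)`` half-open in-plane bounds of voxels that
        carry real data (rather than zero fill introduced by
        translation).  ``None`` means the whole plane is valid.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""
    valid_box: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing[1], self.spacing[2]

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_data(self, data: np.ndarray, **kwargs) -> "SequenceVolume":
        return replace(self, data=data, **kwargs)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine(vol: SequenceVolume) -> np.ndarray:
    # our (slice,row,col) maps to NIfTI (x,y,z) = (col,row,slice)
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def write_nifti(vol: SequenceVolume, path: str | os.PathLike) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data).T, _affine(vol))
    nib.save(img, path)
    return path


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(path)
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off_diag, 0.0):
        raise VolumeFormatError(
            f"{path}: only axis-aligned (diagonal affine) NIfTI volumes are supported"
        )
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got {arr.ndim}-D")
    sx, sy, sz = np.abs(np.diag(aff[:3, :3]))
    ox, oy, oz = aff[:3, 3]
    return arr.T, (float(sz), float(sy), float(sx)), (float(oz), float(oy), float(ox))


# ---------------------------------------------------------------------------
# MetaImage (minimal, uncompressed, ElementDataFile = LOCAL)
# ---------------------------------------------------------------------------

_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_NP_TO_MET = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def write_metaimage(vol: SequenceVolume, path: str | os.PathLike) -> Path:
    path = Path(path)
    data = np.ascontiguousarray(vol.data)
    if data.dtype not in _NP_TO_MET:
        data = data.astype(np.float64)
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    ns, nr, nc = data.shape
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        f"DimSize = {nc} {nr} {ns}\n"
        f"ElementSpacing = {sx:g} {sy:g} {sz:g}\n"
        f"Offset = {ox:g} {oy:g} {oz:g}\n"
        f"ElementType = {_NP_TO_MET[data.dtype]}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(data.tobytes())  # C order: col fastest == x fastest
    return path


def _read_metaimage(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    fields: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise VolumeFormatError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii", errors="replace").partition("=")
            key, value = key.strip(), value.strip()
            fields[key] = value
            if key == "ElementDataFile":
                if value != "LOCAL":
                    raise VolumeFormatError(
                        f"{path}: only ElementDataFile = LOCAL is supported"
                    )
                raw = fh.read()
                break
    try:
        nc, nr, ns = (int(t) for t in fields["DimSize"].split())
        dtype = _MET_TYPES[fields["ElementType"]]
    except KeyError as exc:
        raise VolumeFormatError(f"{path}: missing MetaImage field {exc}") from exc
    if "ElementSpacing" not in fields:
        raise VolumeFormatError(f"{path}: MetaImage header lacks ElementSpacing")
    sx, sy, sz = (float(t) for t in fields["ElementSpacing"].split())
    ox, oy, oz = (
        (float(t) for t in fields["Offset"].split())
        if "Offset" in fields
        else (0.0, 0.0, 0.0)
    )
    if fields.get("BinaryDataByteOrderMSB", "False") == "True":
        dtype = np.dtype(dtype).newbyteorder(">")
    expected = ns * nr * nc * np.dtype(dtype).itemsize
    if len(raw) < expected:
        raise VolumeFormatError(f"{path}: raw payload shorter than DimSize implies")
    arr = np.frombuffer(raw[:expected], dtype=dtype).reshape(ns, nr, nc)
    return arr, (sz, sy, sx), (float(oz), float(oy), float(ox))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_sequence(path: str | os.PathLike, label: str = "") -> SequenceVolume:
    """Read a MetaImage or NIfTI volume, taking spacing/origin from the header."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    try:
        if suffixes.endswith((".mha", ".mhd")):
            data, spacing, origin = _read_metaimage(path)
        elif suffixes.endswith((".nii", ".nii.gz")):
            data, spacing, origin = _read_nifti(path)
        else:
            raise VolumeFormatError(f"{path}: unrecognised volume format")
    except VolumeFormatError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise VolumeFormatError(f"{path}: failed to read volume ({exc})") from exc
    return SequenceVolume(data=data, spacing=spacing, origin=origin, label=label)


def write_sequence(vol: SequenceVolume, path: str | os.PathLike) -> Path:
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mha", ".mhd")):
        return write_metaimage(vol, path)
    if suffixes.endswith((".nii", ".nii.gz")):
        return write_nifti(vol, path)
    raise VolumeFormatError(f"{path}: unrecognised volume format")
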