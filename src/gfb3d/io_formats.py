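"""Volumes, label volumes and morphometry tables with physical metadata.

The common currency of every stage is :class:`ImageVolume`: a 3D scalar grid
indexed ``(z, y, x)`` with a per-axis voxel size in nanometres.  MRC2014 is the
canonical interchange format (modes 0/1/2/6); multi-page TIFF is accepted for
convenience but carries no guaranteed pixel-size metadata, so reading TIFF
requires an explicit ``voxel_size``.  Missing pixel-size metadata is always an
error rather than a silent 1 nm default: every downstream statistic is in
physical units.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "MorphometryRecord",
    "MorphometryTable",
    "read_volume",
    "write_volume",
    "voxel_size_from_fov",
    "read_morphometry_csv",
    "write_morphometry_csv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """3D scalar intensity grid with physical metadata.

    Parameters
    ----------
    data:
        Array indexed ``(z, y, x)``.
    voxel_size:
        Per-axis voxel edge length in nm, ordered ``(z, y, x)``; all > 0.
    origin:
        Physical coordinate (nm) of the centre of voxel ``(0, 0, 0)``.
    meta:
        Free-form provenance (tilt axis of a reconstruction, seeds, ...).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have dimension >= 1")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive lengths, got {self.voxel_size}")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical extent per axis (nm): dimension x voxel size."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size))  # type: ignore[return-value]

    @property
    def physical_volume_nm3(self) -> float:
        ez, ey, ex = self.extent_nm
        return ez * ey * ex


@dataclass
class LabelVolume:
    """Integer compartment labels aligned with an :class:`ImageVolume`.

    ``legend`` maps every label value present to a compartment name; the labels
    partition the grid (each voxel carries exactly one label).
    """

    labels: np.ndarray
    legend: dict[int, str]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend does not cover labels {sorted(missing)}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the compartment called ``name``."""
        values = [v for v, n in self.legend.items() if n == name]
        if not values:
            raise KeyError(f"no label named {name!r} in legend")
        return np.isin(self.labels, values)


@dataclass
class MorphometryRecord:
    """One tracked sub-podocyte space: exit width (nm), length (um), depth (nm)."""

    sps_id: int
    exit_width_nm: float
    length_um: float
    depth_nm: float
    n_exits: int = 0
    sub_resolution: bool = False

    def __post_init__(self) -> None:
        if self.exit_width_nm < 0 or self.length_um < 0 or self.depth_nm < 0:
            raise ValueError("morphometry values must be non-negative")
        if (self.exit_width_nm == 0) != (self.n_exits == 0):
            raise ValueError("exit_width is 0 iff n_exits is 0")


@dataclass
class MorphometryTable:
    records: list[MorphometryRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.sps_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("record ids must be unique")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.sps_id for r in self.records],
                "exit_width_nm": [r.exit_width_nm for r in self.records],
                "length_um": [r.length_um for r in self.records],
                "depth_nm": [r.depth_nm for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_HEADER_BYTES = 1024
_MODE_TO_DTYPE = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_TO_MODE = {np.dtype(np.int8): 0, np.dtype(np.int16): 1, np.dtype(np.float32): 2, np.dtype(np.uint16): 6}


def _mrc_mode_for(dtype: np.dtype) -> int:
    dtype = np.dtype(dtype)
    if dtype in _DTYPE_TO_MODE:
        return _DTYPE_TO_MODE[dtype]
    if np.issubdtype(dtype, np.floating):
        return 2
    if np.issubdtype(dtype, np.integer):
        # widen small signed ints; anything beyond int16 range must be cast first
        info = np.iinfo(dtype)
        if info.min >= -32768 and info.max <= 32767:
            return 1
        raise ValueError(f"integer dtype {dtype} does not fit an MRC mode; cast explicitly")
    raise ValueError(f"unsupported dtype {dtype} for MRC")


def _write_mrc(vol: ImageVolume, path: Path) -> None:
    mode = _mrc_mode_for(vol.data.dtype)
    data = np.ascontiguousarray(vol.data.astype(_MODE_TO_DTYPE[mode], copy=False))
    nz, ny, nx = data.shape
    vz, vy, vx = vol.voxel_size  # nm; MRC cell is in Angstrom
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<10i", header, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", header, 40, nx * vx * 10.0, ny * vy * 10.0, nz * vz * 10.0, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    dmin, dmax, dmean = float(data.min()), float(data.max()), float(data.mean())
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg=1 (volume), nsymbt=0
    oz, oy, ox = vol.origin
    struct.pack_into("<3f", header, 196, ox * 10.0, oy * 10.0, oz * 10.0)
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        data.tofile(fh)


def _read_mrc(path: Path, voxel_size: tuple[float, float, float] | None) -> ImageVolume:
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise IOError(
            f"{path}: truncated MRC header, file ends at byte {len(raw)} of {_MRC_HEADER_BYTES}"
        )
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise IOError(f"{path}: not an MRC2014 file (no 'MAP ' tag at byte 208)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cax, cay, caz = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    ox, oy, oz = struct.unpack_from("<3f", raw, 196)
    if mode not in _MODE_TO_DTYPE:
        raise IOError(f"{path}: unsupported MRC mode {mode}")
    dtype = np.dtype(_MODE_TO_DTYPE[mode])
    start = _MRC_HEADER_BYTES + nsymbt
    expected = start + nx * ny * nz * dtype.itemsize
    if len(raw) < expected:
        raise IOError(
            f"{path}: truncated MRC data, file ends at byte {len(raw)}, expected {expected}"
        )
    data = np.frombuffer(raw[start:expected], dtype=dtype).reshape(nz, ny, nx).copy()
    if voxel_size is None:
        mx, my, mz = mx or nx, my or ny, mz or nz
        if cax <= 0 or cay <= 0 or caz <= 0:
            raise ValueError(
                f"{path}: MRC header carries no cell dimensions; pass voxel_size= explicitly"
            )
        voxel_size = (caz / mz / 10.0, cay / my / 10.0, cax / mx / 10.0)
    return ImageVolume(data, voxel_size, origin=(oz / 10.0, oy / 10.0, ox / 10.0))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        suffix = path.suffix.lower()
        fmt = {"mrc": "mrc", ".mrc": "mrc", ".rec": "mrc", ".st": "mrc",
               ".tif": "tiff", ".tiff": "tiff"}.get(suffix, "mrc")
    if fmt in ("tiff-stack", "tif"):
        fmt = "tiff"
    if fmt not in ("mrc", "tiff"):
        raise ValueError(f"unknown format {format!r}; use 'mrc' or 'tiff'")
    return fmt


def read_volume(path, format: str | None = None,
                voxel_size: tuple[float, float, float] | None = None) -> ImageVolume:
    """Read a 3D volume from MRC2014 or a multi-page TIFF stack.

    ``voxel_size`` (nm, ``(z, y, x)``) overrides file metadata; it is required
    for TIFF, which is accepted without guaranteed metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "mrc":
        return _read_mrc(path, voxel_size)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if voxel_size is None:
        raise ValueError(f"{path}: TIFF carries no trusted pixel size; pass voxel_size= in nm")
    return ImageVolume(data, voxel_size)


def write_volume(vol: ImageVolume, path, format: str | None = None) -> Path:
    """Write a volume; ``read_volume(write_volume(vol))`` reproduces it (MRC)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mrc":
        _write_mrc(vol, path)
    else:
        tifffile.imwrite(path, np.ascontiguousarray(vol.data))
    return path


def voxel_size_from_fov(fov_nm: float, n_pixels: int) -> float:
    """Voxel edge length (nm) from a field of view and a pixel count.

    A 84 000 nm field on a 2048-pixel array gives 41.0 nm, the in-plane voxel
    size of the serial block-face stack.
    """
    if fov_nm <= 0:
        raise ValueError(f"field of view must be positive, got {fov_nm}")
    if n_pixels < 1:
        raise ValueError(f"pixel count must be >= 1, got {n_pixels}")
    return fov_nm / n_pixels


_CSV_COLUMNS = ["id", "exit_width_nm", "length_um", "depth_nm"]


def write_morphometry_csv(table: MorphometryTable, path) -> Path:
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    return path


def read_morphometry_csv(path) -> MorphometryTable:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: morphometry CSV missing columns {missing}")
    records = [
        MorphometryRecord(
            sps_id=int(row["id"]),
            exit_width_nm=float(row["exit_width_nm"]),
            length_um=float(row["length_um"]),
            depth_nm=float(row["depth_nm"]),
            n_exits=0 if float(row["exit_width_nm"]) == 0 else 1,
        )
        for _, row in df.iterrows()
    ]
    return MorphometryTable(records, provenance=str(path))
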