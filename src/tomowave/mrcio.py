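"""Minimal MRC2014 volume/stack I/O.

Self-contained reader/writer for the electron-microscopy MRC format:
reads the common little-endian modes (0 int8, 1 int16, 2 float32,
6 uint16), writes mode 2 (32-bit float).  Axis order on disk follows the
MRC convention (section, row, column) = (z, y, x), which is the in-memory
order used throughout this package.  Voxel size round-trips through the
``cella`` cell-dimension fields.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .image import Image

__all__ = ["read_mrc", "write_mrc", "read_tlt", "write_tlt"]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_BYTES = 1024


def read_mrc(path) -> Image:
    """Read an MRC volume or stack; rejects non-finite voxel values."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz, mode = struct.unpack("<4i", raw[0:16])
    mx, my, mz = struct.unpack("<3i", raw[28:40])
    cella = struct.unpack("<3f", raw[40:52])
    machst = raw[212:214]
    if machst not in (b"\x44\x44", b"\x44\x41", b"\x00\x00"):
        raise ValueError(f"{path}: unsupported (big-endian?) machine stamp")
    if mode not in _MODE_DTYPES:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    count = nx * ny * nz
    offset = _HEADER_BYTES + nsymbt
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    data = data.reshape(nz, ny, nx).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: contains non-finite voxel values")
    spacing = None
    if mx > 0 and my > 0 and mz > 0 and all(c > 0 for c in cella):
        spacing = (cella[2] / mz, cella[1] / my, cella[0] / mx)  # (z, y, x) Å
    vol = data[0] if nz == 1 else data
    if vol.ndim == 2 and spacing is not None:
        spacing = spacing[1:]
    return Image(vol, spacing=spacing)


def write_mrc(path, data, spacing=None) -> None:
    """Write a 2-D image or 3-D volume/stack as MRC2014 mode 2 (float32)."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
        if spacing is not None and len(spacing) == 2:
            spacing = (1.0, *spacing)
    if arr.ndim != 3:
        raise ValueError("MRC writer accepts 2-D or 3-D data")
    nz, ny, nx = arr.shape
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    cella = (nx * spacing[2], ny * spacing[1], nz * spacing[0])
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)      # mx, my, mz
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)         # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(arr.min()), float(arr.max()),
                     float(arr.mean()))
    struct.pack_into("<i", header, 88, 0)                # ispg
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"                # little-endian stamp
    struct.pack_into("<f", header, 216, float(arr.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.tobytes())


def read_tlt(path) -> np.ndarray:
    """Read a plain-text tilt-angle file (one angle in degrees per line)."""
    return np.atleast_1d(np.loadtxt(path, dtype=float))


def write_tlt(path, angles_deg) -> None:
    np.savetxt(path, np.asarray(angles_deg, dtype=float), fmt="%.2f")
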