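"""MRC2014 volume/image-stack I/O.

Data are stored on disk x-fastest; in memory the array is indexed
``(z, y, x)`` slowest-to-fastest (the ``axis_order`` tag on
:class:`VolumeGrid` records this convention explicitly).  Pixel size is
taken from the header cell dimensions divided by the grid size.  Reading
supports modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16); writing
always produces mode 2.  Lengths are Angstrom everywhere in memory;
pixels appear only at this I/O boundary.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["VolumeGrid", "read_mrc", "write_mrc", "MrcFormatError"]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_SIZE = 1024


class MrcFormatError(ValueError):
    """Unsupported or corrupt MRC file."""


@dataclass
class VolumeGrid:
    """A real-space 3D grid (2D images get a singleton z axis).

    data: (nz, ny, nx) array; pixel_size: A/px; origin: 3-vector in A
    (x, y, z order); axis_order: storage convention tag.
    """

    data: np.ndarray
    pixel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_order: str = "zyx"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("VolumeGrid.data must be 3D with all dims >= 1")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)


def read_mrc(path) -> VolumeGrid:
    """Read an MRC2014 file (modes 0/1/2/6, either byte order)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MrcFormatError(f"{path}: truncated header ({len(raw)} bytes)")
    # machine stamp (bytes 212-215) decides endianness; fall back to LE
    machst = raw[212:216]
    endian = ">" if machst[:2] == b"\x11\x11" else "<"
    ints = struct.unpack(endian + "10i", raw[:40])
    nx, ny, nz, mode = ints[0], ints[1], ints[2], ints[3]
    mx, my, mz = ints[7], ints[8], ints[9]
    cella = struct.unpack(endian + "3f", raw[40:52])
    if mode not in _MODE_DTYPES:
        raise MrcFormatError(f"{path}: unsupported MRC mode {mode}")
    nsymbt = struct.unpack(endian + "i", raw[92:96])[0]
    origin = struct.unpack(endian + "3f", raw[196:208])
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder(endian)
    count = nx * ny * nz
    offset = _HEADER_SIZE + nsymbt
    expected = offset + count * dtype.itemsize
    if len(raw) < expected:
        raise MrcFormatError(
            f"{path}: truncated data ({len(raw)} bytes, expected {expected})"
        )
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    data = data.reshape(nz, ny, nx).astype(np.float32)
    px = cella[0] / mx if mx > 0 and cella[0] > 0 else 1.0
    return VolumeGrid(data=data, pixel_size=float(px), origin=np.array(origin, dtype=float))


def write_mrc(vol: VolumeGrid, path) -> None:
    """Write mode-2 (float32) MRC2014; inverse of :func:`read_mrc`."""
    data = np.asarray(vol.data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite data to MRC")
    nz, ny, nx = data.shape
    px = float(vol.pixel_size)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<10i", header, 0, nx, ny, nz, 2, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<3f", header, 40, nx * px, ny * px, nz * px)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    struct.pack_into("<3f", header, 196, *[float(v) for v in vol.origin])
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
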