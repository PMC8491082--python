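"""Minimal LAS 1.2 reader/writer.

Only the geometry the pipeline consumes is handled: x/y/z coordinates and the
per-point classification byte, for point record formats 0-3.  Other attributes
(returns, GPS time, colour) are ignored on read and zero-filled on write.
Coordinates are stored as int32 counts of a scale quantum relative to an
offset, per the LAS specification; the writer picks a 1 mm quantum.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_FMT = "<4sHH16sBB32s32sHHHIIBHI5I3d3d6d"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)  # 227 bytes, LAS 1.2
assert _HEADER_SIZE == 227

# point record length per point data format id
_RECORD_LENGTHS = {0: 20, 1: 28, 2: 26, 3: 34}
_CLASSIFICATION_OFFSET = 15  # byte offset of the classification field


class LasFormatError(ValueError):
    """Raised for unparseable or truncated LAS files."""


def read_las(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Read a LAS 1.x file, returning ``(x, y, z, classification)`` arrays."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < _HEADER_SIZE:
        raise LasFormatError(f"{path}: file shorter than a LAS header")
    fields = struct.unpack_from(_HEADER_FMT, data, 0)
    signature = fields[0]
    if signature != b"LASF":
        raise LasFormatError(f"{path}: missing LASF signature")
    point_format = fields[13] & 0x3F
    record_length = fields[14]
    n_points = fields[15]
    offset_to_points = fields[11]
    if point_format not in _RECORD_LENGTHS:
        raise LasFormatError(f"{path}: unsupported point data format {point_format}")
    if record_length < _RECORD_LENGTHS[point_format]:
        raise LasFormatError(f"{path}: record length {record_length} too small")
    end = offset_to_points + n_points * record_length
    if end > len(data):
        raise LasFormatError(
            f"{path}: truncated point data "
            f"(expected {end} bytes, file has {len(data)})"
        )
    scales = np.asarray(fields[21:24])
    offsets = np.asarray(fields[24:27])

    raw = np.frombuffer(
        data, dtype=np.uint8, count=n_points * record_length, offset=offset_to_points
    ).reshape(n_points, record_length)
    xyz_int = raw[:, :12].copy().view("<i4").reshape(n_points, 3)
    classification = raw[:, _CLASSIFICATION_OFFSET].copy()
    coords = xyz_int * scales + offsets
    return coords[:, 0], coords[:, 1], coords[:, 2], classification


def write_las(
    path: str | Path,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    classification: np.ndarray,
    scale: float = 0.001,
) -> None:
    """Write a point format 0 LAS 1.2 file with classification labels."""
    path = Path(path)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    classification = np.asarray(classification, dtype=np.uint8)
    n = x.size
    if n:
        offsets = np.array([x.min(), y.min(), z.min()])
        maxima = np.array([x.max(), y.max(), z.max()])
    else:
        offsets = np.zeros(3)
        maxima = np.zeros(3)

    record_length = _RECORD_LENGTHS[0]
    header = struct.pack(
        _HEADER_FMT,
        b"LASF",
        0,  # file source id
        0,  # global encoding
        b"\0" * 16,  # GUID
        1,
        2,  # version 1.2
        b"canopylidar".ljust(32, b"\0"),
        b"canopylidar".ljust(32, b"\0"),
        0,
        0,  # creation day / year
        _HEADER_SIZE,
        _HEADER_SIZE,  # offset to point data (no VLRs)
        0,  # number of VLRs
        0,  # point data format
        record_length,
        n,
        n, 0, 0, 0, 0,  # points by return
        scale, scale, scale,
        offsets[0], offsets[1], offsets[2],
        maxima[0], offsets[0],
        maxima[1], offsets[1],
        maxima[2], offsets[2],
    )

    records = np.zeros(n, dtype=np.uint8).reshape(n, 1).repeat(record_length, axis=1)
    xyz_int = np.empty((n, 3), dtype="<i4")
    for i, arr in enumerate((x, y, z)):
        xyz_int[:, i] = np.round((arr - offsets[i]) / scale).astype("<i4")
    records[:, :12] = xyz_int.view(np.uint8).reshape(n, 12)
    records[:, _CLASSIFICATION_OFFSET] = classification
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(records.tobytes())
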