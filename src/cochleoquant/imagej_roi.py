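"""Minimal reader for ImageJ ``.roi`` files and ``.zip`` ROI archives.

Implements the subset of the ImageJ ROI binary format the annotation
workflow produces: multipoint selections (cells) and polyline /
segmented-line selections (the cochlear axis), with integer or sub-pixel
coordinates and the ROI name from the version-2 header.  All fields are
big-endian; coordinates are returned in image pixel units.
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ROI_TYPE_POLYGON",
    "ROI_TYPE_FREELINE",
    "ROI_TYPE_POLYLINE",
    "ROI_TYPE_POINT",
    "ImageJRoi",
    "read_roi_bytes",
    "read_rois",
]

_MAGIC = b"Iout"

ROI_TYPE_POLYGON = 0
ROI_TYPE_FREELINE = 4
ROI_TYPE_POLYLINE = 5
ROI_TYPE_POINT = 10

_OPT_SUB_PIXEL = 128  # options bit: float coordinates appended after ints


@dataclass(frozen=True)
class ImageJRoi:
    """Decoded ROI: type code, name, and (n, 2) coordinate array in pixels."""

    roi_type: int
    name: str
    coordinates: np.ndarray


def read_roi_bytes(data: bytes, default_name: str = "") -> ImageJRoi:
    """Decode a single ``.roi`` blob."""
    if len(data) < 64 or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file (bad magic)")
    version = struct.unpack(">h", data[4:6])[0]
    roi_type = data[6]
    top, left, _bottom, _right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">h", data[16:18])[0]
    options = struct.unpack(">h", data[50:52])[0]
    hdr2_offset = struct.unpack(">i", data[60:64])[0]

    if n <= 0:
        raise ValueError(f"ROI holds no coordinates (type {roi_type})")

    base = 64
    xs_i = np.frombuffer(data, dtype=">i2", count=n, offset=base).astype(float) + left
    ys_i = np.frombuffer(data, dtype=">i2", count=n, offset=base + 2 * n).astype(float) + top
    coords = np.column_stack([xs_i, ys_i])

    if options & _OPT_SUB_PIXEL and version >= 222:
        fbase = base + 4 * n
        if len(data) >= fbase + 8 * n:
            xs_f = np.frombuffer(data, dtype=">f4", count=n, offset=fbase).astype(float)
            ys_f = np.frombuffer(data, dtype=">f4", count=n, offset=fbase + 4 * n).astype(float)
            coords = np.column_stack([xs_f, ys_f])

    name = default_name
    if hdr2_offset > 0 and len(data) >= hdr2_offset + 24:
        name_offset = struct.unpack(">i", data[hdr2_offset + 16 : hdr2_offset + 20])[0]
        name_length = struct.unpack(">i", data[hdr2_offset + 20 : hdr2_offset + 24])[0]
        if name_offset > 0 and name_length > 0:
            raw = data[name_offset : name_offset + 2 * name_length]
            name = raw.decode("utf-16-be", errors="replace")

    return ImageJRoi(roi_type=roi_type, name=name, coordinates=coords)


def read_rois(path: str | Path) -> list[ImageJRoi]:
    """Read one ``.roi`` file or every ROI in a ``.zip`` archive."""
    path = Path(path)
    if path.suffix.lower() == ".zip":
        rois = []
        with zipfile.ZipFile(path) as zf:
            for entry in zf.namelist():
                if not entry.lower().endswith(".roi"):
                    continue
                rois.append(read_roi_bytes(zf.read(entry), default_name=Path(entry).stem))
        return rois
    return [read_roi_bytes(path.read_bytes(), default_name=path.stem)]
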