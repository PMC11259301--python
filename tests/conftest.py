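"""Shared fixtures: CSV writers, an independent ImageJ-ROI byte builder,
and small synthetic datasets."""

from __future__ import annotations

import struct
import zipfile
from pathlib import Path

import numpy as np
import pytest

from cochleoquant import SyntheticCochleaSpec, generate


def build_roi_bytes(
    roi_type: int,
    coords: list[tuple[float, float]],
    name: str,
    subpixel: bool = False,
) -> bytes:
    """Construct an ImageJ ``.roi`` blob directly from the documented
    binary layout (big-endian, 64-byte header, int coords relative to the
    bounding box, optional float coords, version-2 header carrying the
    UTF-16BE name).  Written independently of the package's reader so the
    two act as cross-checks.
    """
    n = len(coords)
    xs = [x for x, _ in coords]
    ys = [y for _, y in coords]
    left, top = int(np.floor(min(xs))), int(np.floor(min(ys)))
    right, bottom = int(np.ceil(max(xs))) + 1, int(np.ceil(max(ys))) + 1

    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    options = 128 if subpixel else 0  # SUB_PIXEL_RESOLUTION
    struct.pack_into(">h", header, 50, options)

    body = bytearray()
    for x in xs:
        body += struct.pack(">h", int(round(x)) - left)
    for y in ys:
        body += struct.pack(">h", int(round(y)) - top)
    if subpixel:
        for x in xs:
            body += struct.pack(">f", x)
        for y in ys:
            body += struct.pack(">f", y)

    hdr2_offset = 64 + len(body)
    struct.pack_into(">i", header, 60, hdr2_offset)
    hdr2 = bytearray(64)
    name_bytes = name.encode("utf-16-be")
    struct.pack_into(">i", hdr2, 16, hdr2_offset + 64)  # name offset
    struct.pack_into(">i", hdr2, 20, len(name))  # name length in chars
    return bytes(header) + bytes(body) + bytes(hdr2) + name_bytes


def write_roi_zip(path: Path, rois: list[tuple[int, list, str]], subpixel: bool = False) -> None:
    with zipfile.ZipFile(path, "w") as zf:
        for roi_type, coords, name in rois:
            zf.writestr(f"{name}.roi", build_roi_bytes(roi_type, coords, name, subpixel))


@pytest.fixture
def roi_builder():
    return build_roi_bytes


@pytest.fixture
def roi_zip_writer():
    return write_roi_zip


@pytest.fixture
def straight_axis_csv(tmp_path: Path) -> Path:
    path = tmp_path / "axis.csv"
    xs = np.linspace(0, 1000, 11)
    path.write_text("x,y\n" + "".join(f"{x},0\n" for x in xs))
    return path


@pytest.fixture(scope="session")
def default_truth():
    """One generated cochlea with constant p = 0.5, reused across tests."""
    return generate(SyntheticCochleaSpec(seed=11)).truth


@pytest.fixture(scope="session")
def bump_truth():
    """Mid-peaked cochlea (known argmax at L/2)."""
    spec = SyntheticCochleaSpec(seed=5, profiles=("gaussian_bump", {}))
    return generate(spec).truth
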