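"""Reading and writing of cell annotations, axis polylines and profiles.

The canonical interchange format is CSV (UTF-8, comma separated, header
row).  Annotation tables carry columns ``x``, ``y``, ``cell_type`` and
optionally ``fragment_id``; axis polylines carry ``x`` and ``y`` in point
order.  ImageJ ROI files (multipoint selections for cells, segmented-line
selections for the axis) are supported as an optional reader because the
annotation workflow is Fiji-based.

Coordinates are converted to micrometres at load time via an explicit
:class:`Calibration`; all downstream computation is in micrometres.  The
image y-axis direction (down-positive) is left untouched: arc length and
point-to-curve projection are invariant under axis flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import imagej_roi

logger = logging.getLogger(__name__)

__all__ = [
    "CELL_TYPES",
    "AnnotationValidationError",
    "AxisPolyline",
    "Calibration",
    "CellAnnotation",
    "FormatError",
    "load_annotations",
    "load_axis",
    "read_profile",
    "register_cell_type",
    "write_annotations",
    "write_axis",
    "write_profile",
]


class FormatError(ValueError):
    """A file does not match the expected layout (missing columns, bad ROI)."""


class AnnotationValidationError(ValueError):
    """A record violates an invariant (unknown label, non-finite coordinate)."""


#: Registry of known cell-type labels.  Seeded with the organ-of-Corti
#: vocabulary: one inner-hair-cell row, three outer-hair-cell rows and the
#: four annotated supporting-cell types (inner phalangeal, Deiters',
#: pillar, inner border).  Extensible via :func:`register_cell_type`.
CELL_TYPES: set[str] = {"IHC", "OHC1", "OHC2", "OHC3", "IPhC", "DC", "PC", "IBC"}


def register_cell_type(label: str) -> None:
    """Add ``label`` to the registry of accepted cell types."""
    if not label or not isinstance(label, str):
        raise ValueError("cell-type label must be a non-empty string")
    CELL_TYPES.add(label)


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel size, in micrometres per pixel."""

    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be finite and > 0, got {self.pixel_size}")


@dataclass(frozen=True)
class CellAnnotation:
    """One annotated (transduced) cell: planar position in μm plus label."""

    x: float
    y: float
    cell_type: str
    fragment_id: str | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise AnnotationValidationError(
                f"unregistered cell type {self.cell_type!r}; known types: {sorted(CELL_TYPES)}"
            )
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise AnnotationValidationError(
                f"non-finite coordinate ({self.x}, {self.y}) for cell type {self.cell_type!r}"
            )


@dataclass(frozen=True)
class AxisPolyline:
    """Ordered control points of a delineated cochlear axis, in μm.

    ``base_first`` is explicit orientation metadata: if True the first
    point is the cochlear base (longitudinal coordinate 0).  Orientation is
    never inferred from geometry.
    """

    points: np.ndarray
    fragment_id: str | None = None
    base_first: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be an (N, 2) array, got shape {pts.shape}")
        pts = _drop_consecutive_duplicates(pts)
        if len(pts) < 2:
            raise AnnotationValidationError(
                "axis polyline needs at least 2 distinct points"
            )
        if not np.all(np.isfinite(pts)):
            raise AnnotationValidationError("axis polyline contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    def oriented_points(self) -> np.ndarray:
        """Control points ordered base→apex."""
        return self.points if self.base_first else self.points[::-1]

    def __len__(self) -> int:
        return len(self.points)


def _drop_consecutive_duplicates(pts: np.ndarray) -> np.ndarray:
    if len(pts) == 0:
        return pts
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
    return pts[keep]


def _is_roi_path(path: Path) -> bool:
    return path.suffix.lower() in {".roi", ".zip"}


def load_annotations(
    path: str | Path,
    calibration: Calibration = Calibration(),
    label_map: Mapping[str, str] | None = None,
    fragment_id: str | None = None,
) -> list[CellAnnotation]:
    """Load cell annotations from a CSV table or an ImageJ ROI archive.

    CSV files must carry columns ``x``, ``y``, ``cell_type`` (and
    optionally ``fragment_id``).  ImageJ multipoint ROIs encode the cell
    type in the ROI name (one multipoint ROI per cell type; ``.zip``
    archives may hold several).  ``label_map`` renames raw labels before
    validation against the cell-type registry; coordinates are multiplied
    by ``calibration.pixel_size``.
    """
    path = Path(path)
    if _is_roi_path(path):
        records = _annotations_from_roi(path)
    else:
        records = _annotations_from_csv(path)

    label_map = dict(label_map or {})
    out: list[CellAnnotation] = []
    for row_idx, (x, y, raw_label, frag) in enumerate(records):
        label = label_map.get(raw_label, raw_label)
        if label not in CELL_TYPES:
            raise AnnotationValidationError(
                f"{path}: row {row_idx}: unregistered cell type {raw_label!r}"
            )
        if not (np.isfinite(x) and np.isfinite(y)):
            raise AnnotationValidationError(
                f"{path}: row {row_idx}: non-finite coordinate ({x}, {y})"
            )
        out.append(
            CellAnnotation(
                x=float(x) * calibration.pixel_size,
                y=float(y) * calibration.pixel_size,
                cell_type=label,
                fragment_id=frag if frag is not None else fragment_id,
            )
        )
    logger.info("loaded %d annotations from %s", len(out), path)
    return out


def _annotations_from_csv(path: Path) -> list[tuple[float, float, str, str | None]]:
    df = pd.read_csv(path, comment="#")
    missing = {"x", "y", "cell_type"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    frags = df["fragment_id"].astype(str) if "fragment_id" in df.columns else None
    records = []
    for i in range(len(df)):
        frag = None if frags is None or pd.isna(df["fragment_id"].iloc[i]) else frags.iloc[i]
        records.append(
            (float(df["x"].iloc[i]), float(df["y"].iloc[i]), str(df["cell_type"].iloc[i]), frag)
        )
    return records


def _annotations_from_roi(path: Path) -> list[tuple[float, float, str, str | None]]:
    rois = imagej_roi.read_rois(path)
    records: list[tuple[float, float, str, str | None]] = []
    for roi in rois:
        if roi.roi_type != imagej_roi.ROI_TYPE_POINT:
            raise FormatError(
                f"{path}: ROI {roi.name!r} is not a multipoint selection "
                f"(type {roi.roi_type})"
            )
        label = roi.name
        for x, y in roi.coordinates:
            records.append((float(x), float(y), label, None))
    return records


def write_annotations(annotations: Iterable[CellAnnotation], path: str | Path) -> None:
    """Write annotations to the canonical CSV layout (coordinates in μm)."""
    rows = [
        {"x": a.x, "y": a.y, "cell_type": a.cell_type, "fragment_id": a.fragment_id}
        for a in annotations
    ]
    df = pd.DataFrame(rows, columns=["x", "y", "cell_type", "fragment_id"])
    df.to_csv(path, index=False, float_format="%.9g")


def load_axis(
    path: str | Path,
    calibration: Calibration = Calibration(),
    base_first: bool = True,
    fragment_id: str | None = None,
) -> AxisPolyline:
    """Load a cochlear-axis polyline from a CSV of ordered points or an
    ImageJ polyline/segmented-line ROI.

    Points are scaled to μm; consecutive duplicates are dropped; order is
    preserved.  ``base_first`` records which end is the cochlear base.
    """
    path = Path(path)
    if _is_roi_path(path):
        rois = imagej_roi.read_rois(path)
        if len(rois) != 1:
            raise FormatError(f"{path}: expected exactly one axis ROI, found {len(rois)}")
        roi = rois[0]
        if roi.roi_type not in (
            imagej_roi.ROI_TYPE_POLYLINE,
            imagej_roi.ROI_TYPE_FREELINE,
            imagej_roi.ROI_TYPE_POLYGON,
        ):
            raise FormatError(
                f"{path}: ROI {roi.name!r} is not a polyline (type {roi.roi_type})"
            )
        pts = np.asarray(roi.coordinates, dtype=float)
    else:
        df = pd.read_csv(path, comment="#")
        missing = {"x", "y"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
        pts = df[["x", "y"]].to_numpy(dtype=float)
    return AxisPolyline(
        points=pts * calibration.pixel_size,
        fragment_id=fragment_id,
        base_first=base_first,
    )


def write_axis(polyline: AxisPolyline, path: str | Path) -> None:
    """Write an axis polyline as an ordered (x, y) CSV in μm."""
    df = pd.DataFrame(polyline.points, columns=["x", "y"])
    df.to_csv(path, index=False, float_format="%.9g")


def write_profile(profile, path: str | Path, header_comment: str | None = None) -> None:
    """Write a transduction profile as tidy CSV.

    Columns are ``position_um``, ``cell_type``, ``fraction`` and
    ``density_cells_per_um``; rows are grouped per cell type with the grid
    repeated per group.  ``header_comment`` lines (if given) are prepended
    prefixed with ``#``.
    """
    frames = []
    for cell_type in sorted(profile.fractions):
        frames.append(
            pd.DataFrame(
                {
                    "position_um": profile.grid,
                    "cell_type": cell_type,
                    "fraction": profile.fractions[cell_type],
                    "density_cells_per_um": profile.densities[cell_type],
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["position_um", "cell_type", "fraction", "density_cells_per_um"]
        )
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_profile(path: str | Path):
    """Read a profile CSV written by :func:`write_profile`."""
    from .cochleogram import TransductionProfile  # deferred: avoids import cycle

    df = pd.read_csv(path, comment="#")
    missing = {"position_um", "cell_type", "fraction", "density_cells_per_um"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    fractions: dict[str, np.ndarray] = {}
    densities: dict[str, np.ndarray] = {}
    grid: np.ndarray | None = None
    for cell_type, grp in df.groupby("cell_type", sort=True):
        g = grp["position_um"].to_numpy(dtype=float)
        if grid is None:
            grid = g
        elif not np.array_equal(grid, g):
            raise FormatError(f"{path}: inconsistent position grids across cell types")
        fractions[str(cell_type)] = grp["fraction"].to_numpy(dtype=float)
        densities[str(cell_type)] = grp["density_cells_per_um"].to_numpy(dtype=float)
    if grid is None:
        grid = np.array([], dtype=float)
    return TransductionProfile(grid=grid, fractions=fractions, densities=densities)
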