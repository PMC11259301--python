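"""Synthetic annotated cochleas with known ground truth.

Generates an Archimedean-type spiral organ of Corti — about two turns,
scaled to a target arc length of 5700 μm — with parallel cell rows laid
at small lateral offsets from the axis: one inner-hair-cell row and three
outer-hair-cell rows at their measured P0 longitudinal densities (IHC
11.8, OHC1 13.7, OHC2 13.9, OHC3 14.1 cells per 100 μm), plus optional
supporting-cell rows with user-supplied densities.  Each cell is marked
transduced by an independent Bernoulli draw with probability p(s) given
by a configurable base→apex profile family, and only transduced cells are
emitted as annotations — mirroring real datasets, in which untransduced
cells are never clicked and totals come from the reference densities.

The full ground truth (every cell, its generative arc-length position,
its transduced flag, the generating axis, and p(s) per type) is returned
alongside, so every pipeline stage can be tested against known truth.
Identical spec + seed reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import (
    CELL_TYPES,
    AxisPolyline,
    CellAnnotation,
    write_annotations,
    write_axis,
)
from .cochleogram import REFERENCE_DENSITIES

__all__ = [
    "DEFAULT_ROW_OFFSETS",
    "GeneratedDataset",
    "SyntheticCochleaSpec",
    "SyntheticGroundTruth",
    "generate",
    "profile_family",
]

#: Lateral offsets of the cell rows from the delineated axis, μm.
#: The axis runs between the IHC row (medial) and the OHC rows (lateral).
DEFAULT_ROW_OFFSETS: dict[str, float] = {
    "IHC": -10.0,
    "OHC1": 8.0,
    "OHC2": 16.0,
    "OHC3": 24.0,
    "IPhC": -5.0,
    "DC": 12.0,
    "PC": 2.0,
    "IBC": -15.0,
}


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"profile parameter {name} must lie in [0, 1], got {value}")
    return value


def profile_family(name: str, params: Mapping | None = None) -> Callable[[np.ndarray], np.ndarray]:
    """Build a transduction-probability profile p(s), s in μm.

    Families (all clipped to [0, 1]):

    - ``constant``: ``level`` everywhere.
    - ``linear``: from ``start`` at s = 0 to ``end`` at s = ``length``.
    - ``logistic``: sigmoid between ``base_level`` and ``apex_level`` with
      midpoint ``center`` and steepness scale ``width`` (μm).  With
      base_level > apex_level this is the basal-peaked decline seen after
      early embryonic injection; reversed it is the apical-rising shape of
      neonatal injections.
    - ``gaussian_bump``: ``baseline`` plus a Gaussian of ``height`` at
      ``center`` with standard deviation ``width`` — a mid-peaked profile.
    """
    p = dict(params or {})
    if name == "constant":
        level = _check_unit("level", p.pop("level", 0.5))
        fn = lambda s: np.full_like(np.asarray(s, dtype=float), level)
    elif name == "linear":
        start = _check_unit("start", p.pop("start", 0.8))
        end = _check_unit("end", p.pop("end", 0.2))
        length = float(p.pop("length", 5700.0))
        fn = lambda s: start + (end - start) * np.asarray(s, dtype=float) / length
    elif name == "logistic":
        base_level = _check_unit("base_level", p.pop("base_level", 0.5))
        apex_level = _check_unit("apex_level", p.pop("apex_level", 0.02))
        center = float(p.pop("center", 1700.0))
        width = float(p.pop("width", 400.0))
        fn = lambda s: apex_level + (base_level - apex_level) / (
            1.0 + np.exp((np.asarray(s, dtype=float) - center) / width)
        )
    elif name == "gaussian_bump":
        baseline = _check_unit("baseline", p.pop("baseline", 0.05))
        height = float(p.pop("height", 0.85))
        _check_unit("baseline + height", baseline + height)
        center = float(p.pop("center", 2850.0))
        width = float(p.pop("width", 570.0))
        fn = lambda s: baseline + height * np.exp(
            -((np.asarray(s, dtype=float) - center) ** 2) / (2.0 * width**2)
        )
    else:
        raise ValueError(
            f"unknown profile family {name!r}; "
            "choose from constant, linear, logistic, gaussian_bump"
        )
    if p:
        raise ValueError(f"unknown parameter(s) for family {name!r}: {sorted(p)}")
    return lambda s: np.clip(fn(s), 0.0, 1.0)


@dataclass(frozen=True)
class SyntheticCochleaSpec:
    """Everything that defines one synthetic cochlea.

    ``profiles`` maps cell types to ``(family_name, params)`` pairs; a
    single pair applies to every generated type.  ``densities`` are in
    cells per 100 μm.  ``cut_positions`` (arc lengths, μm) split the
    cochlea into fragments, emulating a specimen cut during dissection.
    """

    length: float = 5700.0
    inner_radius: float = 150.0
    pitch: float = 280.0
    turns: float = 2.0
    densities: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_DENSITIES)
    )
    row_offsets: Mapping[str, float] = field(default_factory=dict)
    jitter: float = 2.0
    profiles: Mapping[str, tuple[str, Mapping]] | tuple[str, Mapping] = ("constant", {"level": 0.5})
    placement: str = "equal_spacing"
    cut_positions: Sequence[float] = ()
    control_point_spacing: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("target length must be positive")
        if self.turns <= 0 or self.pitch <= 0 or self.inner_radius < 0:
            raise ValueError("spiral needs turns > 0, pitch > 0, inner_radius >= 0")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        if self.placement not in ("equal_spacing", "poisson"):
            raise ValueError(f"unknown placement mode {self.placement!r}")
        for t, d in self.densities.items():
            if d <= 0:
                raise ValueError(f"density for {t!r} must be positive")
            if t not in CELL_TYPES:
                raise ValueError(f"unregistered cell type in densities: {t!r}")
        cuts = sorted(float(c) for c in self.cut_positions)
        for c in cuts:
            if not (0.0 < c < self.length):
                raise ValueError(f"cut position {c} outside (0, {self.length})")
        object.__setattr__(self, "cut_positions", tuple(cuts))

    def profile_for(self, cell_type: str) -> Callable[[np.ndarray], np.ndarray]:
        """Resolved, validated p(s) for one cell type."""
        if isinstance(self.profiles, tuple):
            name, params = self.profiles
        else:
            if cell_type not in self.profiles:
                raise ValueError(f"no transduction profile configured for {cell_type!r}")
            name, params = self.profiles[cell_type]
        return profile_family(name, params)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Complete generated state: every cell, axis, and p(s) per type.

    ``cells`` columns: x, y (μm, jittered planar position), cell_type,
    s_true (generative pre-jitter arc-length position, μm), s_local
    (arc length within the cell's fragment), transduced, fragment_id.
    """

    cells: pd.DataFrame
    axes: dict[str, AxisPolyline]
    fragment_lengths: dict[str, float]
    fragment_order: list[str]
    profiles: dict[str, Callable[[np.ndarray], np.ndarray]]
    L: float

    def transduced_annotations(self, fragment_id: str | None = None) -> list[CellAnnotation]:
        """Transduced cells as annotation records (what an operator clicks)."""
        df = self.cells[self.cells["transduced"]]
        if fragment_id is not None:
            df = df[df["fragment_id"] == fragment_id]
        return [
            CellAnnotation(
                x=float(r.x), y=float(r.y), cell_type=str(r.cell_type),
                fragment_id=str(r.fragment_id),
            )
            for r in df.itertuples()
        ]

    def coords_true(self, transduced_only: bool = True) -> dict[str, np.ndarray]:
        """Ground-truth longitudinal coordinates per cell type."""
        df = self.cells[self.cells["transduced"]] if transduced_only else self.cells
        return {
            str(t): g["s_true"].to_numpy(dtype=float)
            for t, g in df.groupby("cell_type", sort=True)
        }


@dataclass(frozen=True)
class GeneratedDataset:
    """File layout of one generated cochlea plus its ground truth."""

    truth: SyntheticGroundTruth
    annotation_files: dict[str, Path]
    axis_files: dict[str, Path]


class _Spiral:
    """Dense arc-length table of the generating spiral (base at s = 0)."""

    def __init__(self, spec: SyntheticCochleaSpec, step: float = 0.25):
        theta_max = 2.0 * np.pi * spec.turns
        n = max(int(theta_max / 1e-3), 1000)
        theta = np.linspace(0.0, theta_max, n)
        # base is the outer end of the spiral; radius shrinks towards the apex
        r = spec.inner_radius + spec.pitch * (theta_max - theta) / (2.0 * np.pi)
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        seg = np.hypot(np.diff(x), np.diff(y))
        s_raw = np.concatenate([[0.0], np.cumsum(seg)])
        if s_raw[-1] <= 0:
            raise ValueError("spiral parameters give zero arc length")
        scale = spec.length / s_raw[-1]
        self.s = s_raw * scale
        self.xy = np.column_stack([x, y]) * scale
        self.L = float(self.s[-1])
        # unit tangents / normals for lateral row placement
        d = np.gradient(self.xy, self.s, axis=0)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        tangent = d / np.where(norm > 0, norm, 1.0)
        self.normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    def point(self, s: np.ndarray) -> np.ndarray:
        x = np.interp(s, self.s, self.xy[:, 0])
        y = np.interp(s, self.s, self.xy[:, 1])
        return np.column_stack([x, y])

    def unit_normal(self, s: np.ndarray) -> np.ndarray:
        nx = np.interp(s, self.s, self.normal[:, 0])
        ny = np.interp(s, self.s, self.normal[:, 1])
        n = np.column_stack([nx, ny])
        length = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(length > 0, length, 1.0)

    def polyline(self, s_lo: float, s_hi: float, spacing: float) -> np.ndarray:
        n_pts = max(int(np.ceil((s_hi - s_lo) / spacing)) + 1, 2)
        s = np.linspace(s_lo, s_hi, n_pts)
        return self.point(s)


def _place_positions(
    rng: np.random.Generator, L: float, density_per_100um: float, mode: str
) -> np.ndarray:
    spacing = 100.0 / density_per_100um
    if mode == "equal_spacing":
        k = np.arange(int(np.floor(L / spacing + 0.5)))
        return (k + 0.5) * spacing
    n = rng.poisson(L * density_per_100um / 100.0)
    return np.sort(rng.uniform(0.0, L, n))


def generate(
    spec: SyntheticCochleaSpec,
    out_dir: str | Path | None = None,
) -> GeneratedDataset:
    """Generate one synthetic cochlea.

    When ``out_dir`` is given, per-fragment annotation CSVs (transduced
    cells only) and axis-polyline CSVs are written there in the canonical
    formats; the returned ground truth always carries the complete state.
    """
    rng = np.random.default_rng(spec.seed)
    spiral = _Spiral(spec)
    L = spiral.L

    cuts = [0.0, *spec.cut_positions, L]
    fragment_order = [f"frag{j}" for j in range(len(cuts) - 1)]
    fragment_lengths = {
        fid: cuts[j + 1] - cuts[j] for j, fid in enumerate(fragment_order)
    }

    offsets = {**DEFAULT_ROW_OFFSETS, **dict(spec.row_offsets)}
    rows: list[dict] = []
    profiles: dict[str, Callable] = {}
    for cell_type in sorted(spec.densities):
        p_fn = profiles[cell_type] = spec.profile_for(cell_type)
        s = _place_positions(rng, L, float(spec.densities[cell_type]), spec.placement)
        offset = offsets.get(cell_type, 0.0)
        xy = spiral.point(s) + spiral.unit_normal(s) * offset
        if spec.jitter > 0:
            xy = xy + rng.normal(0.0, spec.jitter, size=xy.shape)
        transduced = rng.uniform(0.0, 1.0, size=s.shape) < p_fn(s)
        frag_idx = np.clip(np.searchsorted(cuts, s, side="right") - 1, 0, len(fragment_order) - 1)
        for i in range(len(s)):
            fid = fragment_order[frag_idx[i]]
            rows.append(
                {
                    "x": xy[i, 0],
                    "y": xy[i, 1],
                    "cell_type": cell_type,
                    "s_true": s[i],
                    "s_local": s[i] - cuts[frag_idx[i]],
                    "transduced": bool(transduced[i]),
                    "fragment_id": fid,
                }
            )
    cells = pd.DataFrame(
        rows, columns=["x", "y", "cell_type", "s_true", "s_local", "transduced", "fragment_id"]
    )

    axes = {
        fid: AxisPolyline(
            points=spiral.polyline(cuts[j], cuts[j + 1], spec.control_point_spacing),
            fragment_id=fid,
            base_first=True,
        )
        for j, fid in enumerate(fragment_order)
    }

    annotation_files: dict[str, Path] = {}
    axis_files: dict[str, Path] = {}
    truth = SyntheticGroundTruth(
        cells=cells,
        axes=axes,
        fragment_lengths=fragment_lengths,
        fragment_order=fragment_order,
        profiles=profiles,
        L=L,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fid in fragment_order:
            ann_path = out_dir / f"annotations_{fid}.csv"
            write_annotations(truth.transduced_annotations(fid), ann_path)
            annotation_files[fid] = ann_path
            axis_path = out_dir / f"axis_{fid}.csv"
            write_axis(axes[fid], axis_path)
            axis_files[fid] = axis_path
    return GeneratedDataset(truth=truth, annotation_files=annotation_files, axis_files=axis_files)
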