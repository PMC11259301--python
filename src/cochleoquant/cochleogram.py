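"""Smoothed longitudinal density profiles and transduction-rate conversion.

A *cochleogram* is the Gaussian-smoothed longitudinal density of
transduced cells along the cochlear axis, in cells/μm, evaluated on a
regular grid from base (0) to apex (L):

    λ(x) ∝ Σ_i φ_σ(x − s_i) / w(x)

where φ_σ is the unit-mass Gaussian kernel (σ = 250 μm by default, about
1/20th of the cochlear length) and s_i are the longitudinal coordinates of
the transduced cells.  With boundary correction on, w(x) is the kernel
mass falling inside the domain, ∫₀ᴸ φ_σ(u − x) du — the standard
cut-and-normalize correction, which removes the downward bias an
unrenormalized kernel produces within ~2σ of the base and apex — and the
corrected curve is then rescaled by a single global factor so that it
integrates over [0, L] to exactly the number of cells (the count is known,
so the density is pinned to it; the factor is within a fraction of a
percent of 1).  With correction off, w ≡ 1 and no rescaling is applied.

Dividing λ by a reference longitudinal cell density (cells per 100 μm,
measured in uninjected cochleas) yields the *transduction profile*: the
local fraction of cells of that type that are transduced.  The reference
values for P0 hair cells are IHC 11.8, OHC1 13.7, OHC2 13.9, OHC3 14.1
cells per 100 μm.  Fractions are not clamped at 1; local densities above
the reference are diagnostic and are surfaced as warnings when the
fraction exceeds 1.05 anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "DEFAULT_SIGMA",
    "DEFAULT_GRID_STEP",
    "REFERENCE_DENSITIES",
    "Cochleogram",
    "FragmentCoordinates",
    "TransductionProfile",
    "combine_fragments",
    "compute_cochleogram",
    "resample_relative",
    "to_fraction",
]


class ConfigurationError(ValueError):
    """A required configuration entry (e.g. a reference density) is missing."""


#: Gaussian window standard deviation, μm.
DEFAULT_SIGMA = 250.0

#: Cochleogram evaluation grid step, μm (≪ σ; values between grid points
#: are defined by linear interpolation).
DEFAULT_GRID_STEP = 10.0

#: Reference longitudinal densities of P0 hair cells, cells per 100 μm.
#: No reference values exist for supporting-cell types; they must be
#: supplied explicitly when supporting-cell profiles are normalized.
REFERENCE_DENSITIES: dict[str, float] = {
    "IHC": 11.8,
    "OHC1": 13.7,
    "OHC2": 13.9,
    "OHC3": 14.1,
}


@dataclass(frozen=True)
class Cochleogram:
    """Per-cell-type smoothed density of transduced cells (cells/μm)."""

    grid: np.ndarray
    densities: dict[str, np.ndarray]
    L: float
    sigma: float
    boundary_correction: bool
    n_cells: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class TransductionProfile:
    """Per-cell-type fraction of transduced cells vs longitudinal position."""

    grid: np.ndarray
    fractions: dict[str, np.ndarray]
    densities: dict[str, np.ndarray]
    references: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def L(self) -> float:
        return float(self.grid[-1]) if len(self.grid) else 0.0

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.fractions)


@dataclass(frozen=True)
class FragmentCoordinates:
    """Per-type longitudinal coordinates measured within one cochlear
    fragment, together with that fragment's own axis length."""

    coords: Mapping[str, np.ndarray]
    L: float
    fragment_id: str | None = None


def _make_grid(L: float, grid_step: float) -> np.ndarray:
    n = int(np.floor(L / grid_step + 1e-9)) + 1
    grid = np.arange(n, dtype=float) * grid_step
    if grid[-1] < L - 1e-9:  # always include the apex endpoint
        grid = np.append(grid, L)
    else:
        grid[-1] = min(grid[-1], L)
    return grid


def compute_cochleogram(
    coords: Mapping[str, Sequence[float] | np.ndarray],
    L: float,
    sigma: float = DEFAULT_SIGMA,
    grid_step: float = DEFAULT_GRID_STEP,
    boundary_correction: bool = True,
) -> Cochleogram:
    """Gaussian running-average density of transduced cells along the axis.

    ``coords`` maps each cell type to the longitudinal coordinates (μm) of
    its transduced cells; all coordinates must lie in [0, L].  Returns the
    density λ (cells/μm) on a regular grid of step ``grid_step`` covering
    [0, L].  With ``boundary_correction`` each grid value is divided by the
    in-domain kernel mass w(x) and the curve is rescaled to integrate to
    the cell count exactly.
    """
    if L <= 0:
        raise ValueError(f"axis length must be positive, got {L}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if grid_step <= 0:
        raise ValueError(f"grid_step must be positive, got {grid_step}")

    grid = _make_grid(L, grid_step)

    densities: dict[str, np.ndarray] = {}
    n_cells: dict[str, int] = {}
    for cell_type, s in coords.items():
        s = np.asarray(s, dtype=float)
        if s.size and (s.min() < -1e-9 or s.max() > L + 1e-9):
            raise ValueError(
                f"{cell_type}: longitudinal coordinate outside [0, {L}] "
                f"(range {s.min():.1f}..{s.max():.1f})"
            )
        if s.size == 0:
            lam = np.zeros_like(grid)
        else:
            s = np.sort(s)  # fixed summation order: exact permutation invariance
            lam = np.zeros_like(grid)
            # chunked kernel sum bounds the (n_grid × n_cells) matrix
            chunk = max(1, int(4e6) // max(len(grid), 1))
            for start in range(0, s.size, chunk):
                block = s[start : start + chunk]
                lam += stats.norm.pdf(grid[:, None] - block[None, :], scale=sigma).sum(axis=1)
            if boundary_correction:
                w = stats.norm.cdf((L - grid) / sigma) - stats.norm.cdf(-grid / sigma)
                lam /= w
                mass = np.trapezoid(lam, grid)
                if mass > 0:
                    lam *= s.size / mass
        densities[cell_type] = lam
        n_cells[cell_type] = int(s.size)

    return Cochleogram(
        grid=grid,
        densities=densities,
        L=float(L),
        sigma=float(sigma),
        boundary_correction=bool(boundary_correction),
        n_cells=n_cells,
    )


def to_fraction(
    cochleogram: Cochleogram,
    refs: Mapping[str, float] | None = None,
    metadata: Mapping | None = None,
) -> TransductionProfile:
    """Convert a cochleogram (cells/μm) to a fraction-transduced profile.

    ``refs`` maps cell types to reference longitudinal densities in cells
    per 100 μm (defaults to the P0 hair-cell values).  Each profile is
    f(x) = λ(x) / (ref / 100).  A missing reference for a type present in
    the cochleogram raises :class:`ConfigurationError`.
    """
    refs = dict(REFERENCE_DENSITIES if refs is None else refs)
    fractions: dict[str, np.ndarray] = {}
    used: dict[str, float] = {}
    for cell_type, lam in cochleogram.densities.items():
        if cell_type not in refs:
            raise ConfigurationError(
                f"no reference density configured for cell type {cell_type!r}"
            )
        ref = float(refs[cell_type])
        if not np.isfinite(ref) or ref <= 0:
            raise ConfigurationError(
                f"reference density for {cell_type!r} must be > 0, got {ref}"
            )
        f = lam / (ref / 100.0)
        if np.any(f > 1.05):
            logger.warning(
                "%s: fraction exceeds 1.05 (max %.3f) — local density above the "
                "reference of %.1f cells/100 μm",
                cell_type,
                float(f.max()),
                ref,
            )
        fractions[cell_type] = f
        used[cell_type] = ref
    return TransductionProfile(
        grid=cochleogram.grid,
        fractions=fractions,
        densities=dict(cochleogram.densities),
        references=used,
        metadata=dict(metadata or {}),
    )


def combine_fragments(
    fragments: Sequence[FragmentCoordinates],
    sigma: float = DEFAULT_SIGMA,
    grid_step: float = DEFAULT_GRID_STEP,
    boundary_correction: bool = True,
    refs: Mapping[str, float] | None = None,
) -> TransductionProfile:
    """Merge per-fragment longitudinal coordinates into one whole-cochlea
    profile.

    ``fragments`` must be supplied in explicit base→apex order; the
    ordering is never inferred.  Coordinates of fragment j are offset by
    the summed lengths of the fragments before it, and a single
    cochleogram is computed on the concatenated domain of length ΣL_j,
    then normalized by the reference densities.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValueError("no fragments supplied")
    offsets = np.concatenate([[0.0], np.cumsum([f.L for f in fragments])])
    if not np.all(np.diff(offsets) > 0):
        raise ValueError("every fragment must have a positive axis length")
    L_total = float(offsets[-1])

    merged: dict[str, list[np.ndarray]] = {}
    for frag, off in zip(fragments, offsets[:-1]):
        for cell_type, s in frag.coords.items():
            s = np.asarray(s, dtype=float)
            if s.size and (s.min() < -1e-9 or s.max() > frag.L + 1e-9):
                raise ValueError(
                    f"fragment {frag.fragment_id!r}: coordinate outside [0, {frag.L}]"
                )
            merged.setdefault(cell_type, []).append(s + off)
    coords = {k: np.concatenate(v) if v else np.array([]) for k, v in merged.items()}

    cg = compute_cochleogram(
        coords,
        L=L_total,
        sigma=sigma,
        grid_step=grid_step,
        boundary_correction=boundary_correction,
    )
    meta = {"fragments": [f.fragment_id for f in fragments], "fragment_lengths": [f.L for f in fragments]}
    return to_fraction(cg, refs=refs, metadata=meta)


def resample_relative(profile: TransductionProfile, n_points: int = 100) -> TransductionProfile:
    """Resample a profile onto a uniform relative-position grid [0, 1].

    Linear interpolation; endpoint values are preserved.  Needed to
    average or compare cochleas of unequal length.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be at least 2, got {n_points}")
    if len(profile.grid) < 2:
        raise ValueError("profile grid too short to resample")
    L = profile.grid[-1]
    rel_src = profile.grid / L
    rel_grid = np.linspace(0.0, 1.0, n_points)
    fractions = {
        k: np.interp(rel_grid, rel_src, v) for k, v in profile.fractions.items()
    }
    densities = {
        k: np.interp(rel_grid, rel_src, v) for k, v in profile.densities.items()
    }
    meta = dict(profile.metadata)
    meta["relative_grid"] = True
    meta["source_length_um"] = float(L)
    return TransductionProfile(
        grid=rel_grid,
        fractions=fractions,
        densities=densities,
        references=dict(profile.references),
        metadata=meta,
    )
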