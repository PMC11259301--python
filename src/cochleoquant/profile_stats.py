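"""Statistical comparison of transduction profiles and summary metrics.

Longitudinal profiles are compared with the two-sample Kolmogorov-Smirnov
test applied to the transduced-cell longitudinal coordinates themselves —
the data the smoothed profiles are built from — rather than to smoothed
grid values, whose serial correlation would invalidate the test.  Mean
values (e.g. per-cochlea peak rates) are compared with Welch's t-test
(unequal variances, Welch–Satterthwaite degrees of freedom).  Segment
counts support base/mid/apex comparisons, and peak summaries aggregate to
mean ± SEM across cochleas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "PeakSummary",
    "aggregate_peaks",
    "compare_means_welch",
    "compare_profiles_ks",
    "peak_summary",
    "pool_coordinates",
    "segment_counts",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-sample test."""

    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    grouping: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        if not np.isfinite(self.statistic):
            raise ValueError(f"non-finite statistic: {self.statistic}")


@dataclass(frozen=True)
class PeakSummary:
    """Peak transduction fraction of one cell type in one cochlea."""

    cell_type: str
    peak_fraction: float
    peak_position_um: float
    peak_position_relative: float
    cochlea_id: str | None = None


def pool_coordinates(coords: Mapping[str, np.ndarray]) -> np.ndarray:
    """Pool per-type longitudinal coordinates into one flat sample."""
    arrays = [np.asarray(v, dtype=float) for v in coords.values()]
    return np.concatenate(arrays) if arrays else np.array([], dtype=float)


def compare_profiles_ks(
    coords_a: Sequence[float] | np.ndarray,
    coords_b: Sequence[float] | np.ndarray,
    relative: bool = False,
    length_a: float | None = None,
    length_b: float | None = None,
    grouping: str = "",
) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test on longitudinal coordinates.

    With ``relative=True`` each sample is first divided by its own
    cochlear length (required, via ``length_a`` / ``length_b``), so that
    cochleas of unequal length are compared on a common [0, 1] scale.
    Returns the KS statistic D and its asymptotic two-sided p-value.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison requires two nonempty samples")
    if relative:
        if length_a is None or length_b is None:
            raise ValueError("relative=True requires explicit cochlear lengths")
        a = a / length_a
        b = b / length_b
    res = stats.ks_2samp(a, b, method="asymp")
    return ComparisonResult(
        test="ks_2samp",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        grouping=grouping,
    )


def compare_means_welch(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
    grouping: str = "",
) -> ComparisonResult:
    """Welch's t-test (unequal variances) on two groups of scalars.

    Each group needs at least 2 values and nonzero variance, otherwise
    the Welch degrees of freedom are undefined.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if g.size < 2:
            raise ValueError(f"group {name} has fewer than 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("Welch's test is undefined when both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        test="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        grouping=grouping,
    )


def segment_counts(
    coords: Sequence[float] | np.ndarray,
    L: float,
    n_segments: int = 3,
) -> np.ndarray:
    """Count cells in equal-length longitudinal segments.

    Segments are half-open [kL/n, (k+1)L/n) except the last, which is
    closed so a coordinate exactly at L is counted apically.  The default
    of 3 segments matches the base/mid/apex vocabulary.
    """
    if n_segments < 1:
        raise ValueError(f"n_segments must be >= 1, got {n_segments}")
    s = np.asarray(coords, dtype=float)
    if s.size and (s.min() < -1e-9 or s.max() > L + 1e-9):
        raise ValueError(f"coordinates outside [0, {L}]")
    idx = np.floor(s * n_segments / L).astype(int)
    idx = np.clip(idx, 0, n_segments - 1)
    return np.bincount(idx, minlength=n_segments)


def peak_summary(profile) -> dict[str, PeakSummary]:
    """Per-cell-type peak fraction and its longitudinal position.

    Ties resolve to the first (most basal) grid point attaining the
    maximum.  The cochlea id, if any, is read from the profile metadata.
    """
    if not profile.fractions or len(profile.grid) == 0:
        raise ValueError("cannot summarize an empty profile")
    L = profile.grid[-1] if profile.grid[-1] > 0 else 1.0
    cochlea_id = profile.metadata.get("cochlea_id")
    out: dict[str, PeakSummary] = {}
    for cell_type, f in profile.fractions.items():
        k = int(np.argmax(f))  # argmax returns the first maximum
        out[cell_type] = PeakSummary(
            cell_type=cell_type,
            peak_fraction=float(f[k]),
            peak_position_um=float(profile.grid[k]),
            peak_position_relative=float(profile.grid[k] / L),
            cochlea_id=cochlea_id,
        )
    return out


def aggregate_peaks(
    summaries: Iterable[PeakSummary],
) -> dict[str, dict[str, float]]:
    """Aggregate peak summaries across cochleas: mean ± SEM per cell type."""
    groups: dict[str, list[float]] = {}
    for s in summaries:
        groups.setdefault(s.cell_type, []).append(s.peak_fraction)
    out: dict[str, dict[str, float]] = {}
    for cell_type, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        sem = float(stats.sem(arr)) if arr.size > 1 else float("nan")
        out[cell_type] = {
            "mean": float(arr.mean()),
            "sem": sem,
            "n": int(arr.size),
        }
    return out
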