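# Methods

## Data model

The pipeline consumes three things per cochlea (or per cochlear fragment,
when a specimen was cut during dissection): a table of annotated
transduced cells (planar position + cell-type label), an ordered polyline
tracing the organ of Corti from base to apex, and a pixel-size calibration
(μm/pixel, isotropic). Coordinates are converted to micrometres at load
time and everything downstream works in physical units, because the
smoothing scale (σ = 250 μm) and the reference densities are physical.
The canonical interchange format is CSV; ImageJ `.roi`/`.zip` files
(multipoint selections named by cell type, segmented-line axis) are read
natively since the annotation workflow is Fiji-based. The image y-axis
direction is deliberately not normalized: arc length and point-to-curve
distance are invariant under axis flips, so a down-positive y changes
nothing. The cell-type vocabulary (IHC, OHC1–3, IPhC, DC, PC, IBC) is a
registry, extensible to other epithelia.

Only *transduced* cells are annotated — nobody clicks the negative cells —
so absolute totals enter through reference densities (below), and the
synthetic generator mirrors exactly this data model.

## Axis fitting and projection

The operator's polyline is fitted with a parametric cubic spline under
chord-length parameterization. The default is an interpolating fit
(smoothing 0): the delineation *is* the operator's statement of where the
axis runs, and smoothing it away would second-guess them; a nonnegative
smoothing factor is available, guarded by a fidelity check that rejects
fits straying more than 2 μm (configurable) from any control point. Arc
length is accumulated by chord summation over a dense evaluation of the
curve with step ≤ 1 μm; the error of that quadrature is O(step²) and
negligible against cellular scales. Base maps to s = 0, apex to s = L.

Each cell is projected to the globally nearest point of the dense table
(ties resolve to the smallest s, deterministically), then refined by
bounded continuous minimization of the squared distance on the bracketing
parameter interval, with a guard that the refined point is never worse
than the grid point. Points projecting beyond the curve ends are clamped
to s ∈ [0, L] with the distance measured to the endpoint. Because a
spiral's adjacent turns are candidate nearest neighbours, an acceptance
gate `max_distance` (default 150 μm) rejects cells farther than that from
the curve: organ-of-Corti rows lie within a few tens of μm of the axis
while adjacent turns are ≳250 μm away, so the gate turns potential
misprojection into an explicit, logged rejection count rather than a
silent error.

## The cochleogram and its boundary correction

The smoothed longitudinal density of transduced cells (cells/μm) on a
regular 10 μm grid (≪ σ; values between grid points are defined by linear
interpolation) is

λ(x) ∝ Σᵢ φ_σ(x − sᵢ) / w(x),

with φ_σ the unit-mass Gaussian kernel, σ defaulting to 250 μm
(about 1/20 of the cochlear length). Unit mass — rather than unit peak —
is what makes the division by a reference density (cells per 100 μm)
dimensionally meaningful; the alternative normalization would change
profiles by the constant factor σ√(2π).

Near the base and apex an unrenormalized kernel estimate is biased low,
because part of each kernel's mass falls outside [0, L]. With boundary
correction on (the default), the estimate is divided by the in-domain
kernel mass w(x) = ∫₀ᴸ φ_σ(u − x) du — the standard cut-and-normalize
correction, which restores flat densities to flatness right up to the
domain ends — and then rescaled by a single global factor so that the
curve integrates over [0, L] to exactly the observed cell count. The
rescale exists because cut-and-normalize alone conserves mass only
approximately (each cell contributes ∫φ/w ≠ 1 depending on its distance
to an edge; at realistic per-type counts of ~100–700 cells the error
fluctuates by up to ~0.6%); the cell count is known exactly, so pinning
the integral to it costs nothing and makes "the profile integrates to the
number of cells" an identity. The factor stays within a fraction of a
percent of 1 in practice. Correction can be switched off for
fidelity-to-uncorrected-workflow studies; interior values (≳4σ from the
ends) then differ only by the global factor.

Cell coordinates are sorted before kernel summation so that the profile
is bit-exactly independent of input ordering.

## Fraction conversion

Dividing each type's density by its reference longitudinal density —
IHC 11.8, OHC1 13.7, OHC2 13.9, OHC3 14.1 cells per 100 μm for the P0
cochlea — yields the fraction-transduced profile f(x). Supporting-cell
types have no established reference values; they must be supplied
explicitly in configuration, and a missing reference is a hard error
naming the type, never a silent default. Fractions are not clamped at 1:
f > 1 means the local density exceeded the reference (annotation
duplicates, a locally denser row, or a low reference) and is surfaced as
a warning whenever f exceeds 1.05 anywhere, because it is diagnostic
rather than impossible.

Fragmented cochleas are merged by offsetting fragment j's coordinates by
the summed axis lengths of the fragments before it (the base→apex
fragment order is explicit user input, never inferred) and computing one
cochleogram on the concatenated domain. Profiles of cochleas with
different lengths are brought onto a common footing by linear resampling
onto a relative [0, 1] grid.

## Statistics

Longitudinal profiles are compared with the two-sample Kolmogorov–Smirnov
test applied to the transduced-cell coordinates themselves, not to the
smoothed curves: grid values of a kernel-smoothed profile are strongly
serially correlated, and a KS test on them would be invalid. Samples are
length-normalized by default before comparison (cochleas differ in
length); p-values are asymptotic. Mean values are compared with Welch's
t-test (unequal variances, Welch–Satterthwaite degrees of freedom); the
test refuses both-groups-constant input, where the statistic is
undefined. Segment counts use equal-length half-open segments (last
closed, so s = L counts apically), defaulting to three segments matching
the base/mid/apex vocabulary; the `compare` command's Welch variant
compares per-type, per-segment counts of two datasets. Per-cochlea peak
summaries take the per-type maximum of f (first grid point on ties) and
aggregate across cochleas as mean ± SEM. No multiple-testing correction
is applied.

## Synthetic cochleas

The generator emulates the measured data's structure: an Archimedean-type
spiral (default 2 turns, inner radius 150 μm, pitch 280 μm, rescaled to a
target arc length of 5700 μm), cell rows at small lateral offsets from
the axis (IHC medial at −10 μm; OHC1–3 lateral at 8/16/24 μm), cells
placed along arc length at the reference densities (equal spacing by
default, Poisson optional), positional jitter of 2 μm keeping rows
distinguishable, and an independent Bernoulli transduction draw per cell
with probability p(s). Four p(s) families cover the empirically observed
shapes: constant, linear, logistic (basal-peaked decline or apical rise),
and Gaussian bump (mid-peaked); parameters are validated to [0, 1] before
clipping. Only transduced cells are written as annotations; the returned
ground truth carries every cell, its generative (pre-jitter) arc-length
position, its fragment assignment, and the evaluable p(s). Identical
spec + seed reproduces byte-identical files. Axis "delineation" is
emulated by sampling the spiral every 75 μm, similar to an operator's
click spacing.

What the generator does *not* emulate: annotation errors (missed or
double-clicked cells, mistyped rows), local density variations of the
real epithelium, tissue deformation from flattening the whole-mount, and
any AAV biology — p(s) is purely phenomenological. Passing tests
therefore demonstrate the correctness of the geometry, smoothing,
normalization and statistics on faithful input, not robustness to
annotation noise.

## Verification and problem sizes

The test suite checks each stage against independent oracles: analytic
arc lengths (straight line, quarter circle), brute-force nearest-point
search on a 0.25 μm discretization (1000 random points within 100 μm of a
spiral, agreement within 1 μm), the closed-form Gaussian peak for a
single cell, flat-density recovery for equally spaced cells, a by-hand
Welch computation, rigid-motion/reversal/permutation invariances, and
byte-level determinism. End-to-end, the pipeline recovers each p(s)
family with mean absolute error < 0.05 over the interior (≥ 2σ from the
ends) averaged over 20 seeds, conserves counts to machine precision,
reproduces a cut-and-merged cochlea within 0.05 of the uncut analysis
away from the cut ± 2σ, and holds KS/Welch type-I error in [0.03, 0.07]
at α = 0.05 over 500 null replicates with KS power > 0.9 separating
basal-peaked from apical-rising transduction at 300 cells per group.
`scripts/acceptance.py` recomputes all of these from scratch (~½ minute
on one CPU); the replicate counts above are the sizes it uses.

## Known limitations

- 2D only: maximum-intensity projections are analyzed; a strongly
  non-planar mount would need a 3D axis.
- The projection gate assumes adjacent spiral turns are farther from the
  axis than annotated cells; extremely tight spirals (turn spacing below
  ~2× the gate) would need a smaller `max_distance`.
- Reference densities are treated as exact constants; their sampling
  uncertainty is not propagated into f(x).
- The KS comparison treats cells as independent draws; spatial clustering
  of transduction events would make it anticonservative.
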