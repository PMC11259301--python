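# cochleoquant

Quantification of AAV transduction along the cochlea from point-annotated
whole-mount images.

## The problem

Gene-therapy and developmental studies of the inner ear need to know *what
fraction of each cell type a viral vector transduces, and where along the
cochlea*. The organ of Corti is a spiral ribbon of cells — one row of inner
hair cells (IHC), three rows of outer hair cells (OHC1–3), and several
supporting-cell types (IPhC, DC, PC, IBC) — running ~5700 μm from base to
apex, and transduction efficiency varies strongly along that axis. The
standard readout is a whole-mount confocal image in which an operator clicks
every transduced (reporter-positive) cell with the Fiji multipoint tool and
delineates the spiral axis with the segmented-line tool. `cochleoquant`
turns those annotations into quantitative longitudinal profiles and the
statistics to compare them.

## The method

For each annotated cell with planar position **pᵢ**, the longitudinal
coordinate sᵢ ∈ [0, L] is its arc-length distance from the cochlear base
along the delineated axis, obtained by fitting an arc-length-parameterized
cubic spline to the operator's polyline and projecting **pᵢ** onto it
(global nearest point, with a 150 μm acceptance gate that flags
off-epithelium outliers). The *cochleogram* is the Gaussian-smoothed
density of transduced cells,

&nbsp;&nbsp;λ(x) ∝ Σᵢ φ_σ(x − sᵢ) / w(x),&nbsp;&nbsp;σ = 250 μm (≈ L/20),

where w(x) is the kernel mass inside [0, L] (boundary correction) and the
curve is rescaled to integrate exactly to the cell count. Dividing by a
reference longitudinal density ρ_ref (cells/100 μm; IHC 11.8, OHC1 13.7,
OHC2 13.9, OHC3 14.1 at P0) gives the *transduction profile*

&nbsp;&nbsp;f(x) = λ(x) / (ρ_ref / 100),

the local fraction of cells of that type that are transduced. Cochleas cut
into pieces during dissection are handled by concatenating per-fragment
coordinates with arc-length offsets. Profiles are compared with the
two-sample Kolmogorov–Smirnov test on the cell coordinates themselves
(length-normalized by default) and mean values with Welch's t-test;
per-cochlea peak rates aggregate to mean ± SEM.

A fully synthetic generator produces spiral cochleas with known geometry,
cell rows at the reference densities, and Bernoulli transduction under
configurable base→apex probability profiles p(s) — so the entire pipeline
is testable against ground truth without any imaging data.

## Worked example

```sh
$ cochleoquant generate --seed 1 --out data
generated 3050 cells (1507 transduced) on L = 5700 μm in 1 fragment(s) -> data

$ cochleoquant profile --annotations data/annotations_frag0.csv \
    --axis data/axis_frag0.csv --out run
profile over L = 5700 μm -> run/profile.csv
```

The generator placed 3050 cells on a 5700 μm spiral (four hair-cell rows at
their P0 densities) and transduced each with probability 0.5, so 1507 cells
were "clicked". The profile run fits the axis, projects the annotations and
writes `profile.csv` (tidy per-type fractions and densities on a 10 μm
grid), `peaks.csv`, and `profile.png`:

```
# cochleoquant 0.1.0
# config digest 592adfe83c3d
cell_type,peak_fraction,peak_position_um,peak_position_relative
IHC,0.589856566,2790,0.489473389644
OHC1,0.564549878174,4900,0.859648605469
OHC2,0.581394248338,1800,0.315789283642
OHC3,0.596956291459,4370,0.766666205285
```

Each type's profile fluctuates around the true transduction probability
0.5 (peaks ≈ 0.56–0.60 are sampling noise at these cell counts); the header
records the package version and a digest of the run configuration so
outputs are auditable. `cochleoquant compare --config-a a.yaml --config-b
b.yaml --test both` writes KS and Welch comparisons of two datasets.

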