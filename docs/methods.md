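# Methods

## Scope and model overview

The package studies how the internal refractive-index statistics of a cell
nucleus imprint on its azimuth-resolved light-scattering pattern.  A nucleus
is modelled as a sphere (radius `R`) or an axis-aligned ellipsoid
(semi-axes `Sx, Sy, Sz` along the lab x, y, z) of mean refractive index `n`,
embedded in homogeneous cytoplasm of index `n_out` — a reasonable idealization
for epithelial cells, whose cytoplasm has a low organelle volume fraction.
Inside the nuclear surface the index is

    n(x) = n + δn · g(x),

where `g` is a zero-mean, unit-variance Gaussian random field with isotropic
correlation `C(r) = exp(-r²/lc²)`.  Two parameters summarize the internal
structure: the correlation length `lc` (µm) and the fluctuation extent `δn`.

### Parameter grids and defaults

Three model families are enumerated by `nuclear_models.parameter_grid`:

| family | geometry | n | n_out |
|---|---|---|---|
| `table1_dense` | sphere, R ∈ {3.5, **4.0**, 4.5} µm | {1.39, **1.40**, 1.41} | 1.36 |
| `table1_inverted` | sphere, same radii | {1.35, **1.36**, 1.37} | 1.40 |
| `table2` | ellipsoid, Sx ∈ {2.5, **3.0**, 3.5}, Sy ∈ {4.5, **5.0**, 5.5}, Sz ∈ {3.5, **4.0**, 4.5} µm | {1.39, **1.40**, 1.41} | 1.36 |

with `lc ∈ {0.4 … 1.0}` µm (default 0.7) and `δn ∈ {0.005 … 0.035}`
(default 0.020); bold values are the defaults held fixed while another
parameter is swept.  The `lc` range 0.4–1.0 µm is the realistic span of
chromatin correlation lengths in cervical epithelium, as established by
image analysis of a 937-nucleus stained-biopsy cohort; the `δn` range covers
the fluctuation extents discussed in the disorder-strength literature.

### Interpretation of δn

δn is defined here as the *population standard deviation* of the un-clipped
fluctuation field.  A Gaussian field is unbounded, so an amplitude-bound
reading has no stable single-parameter meaning; the realized sample standard
deviation of each built model is recorded in its provenance
(`RefractiveIndexVolume.realized_std`).  Fluctuations large enough to push
any voxel index to 1 or below are refused as unphysical.  The fluctuation
field is re-centered over the nuclear mask before scaling, so the masked
sample mean equals `n` to ~1e-15 for every seed: size and mean-index sweeps
are not confounded by finite-sample drift of the mean.

### Voxelization

Models are built on an isotropic grid (default pitch 0.05 µm for model
construction; the sweep default is 0.1 µm, which still resolves the smallest
`lc` of 0.4 µm at 4 voxels per correlation length and satisfies the Born
solver's q-space sampling bound of ~0.147 µm at 800 nm).  Voxels are
classified by the voxel-center rule; the grid extends 3 voxels of cytoplasm
beyond the surface.

## Gaussian random field synthesis

Two routes generate `g`:

* **Spectral (default).**  White noise on a padded grid is filtered by the
  square root of the spectral density of `C(r)`; for the Gaussian
  correlation this is ∝ `exp(-k² lc² / 4)`.  The discrete filter is
  normalized so the synthesized field has population variance exactly 1
  (`Var f = (1/N) Σ_k H_k²`).  Grids are padded by ≥ 4·lc per side and
  cropped, removing circular-correlation bias; when `lc` exceeds the domain
  the padding is capped at four domain lengths (the field is then constant
  over the grid to first order and wrap correlation is harmless).
* **Turning bands.**  1000 lines by default, with directions quasi-uniform
  on the sphere via a Fibonacci lattice.  For a 3D isotropic target `C3` the
  1D line covariance must satisfy `C1(s) = d/ds [s C3(s)]`; for the Gaussian
  target `C1(s) = exp(-s²/lc²)(1 − 2s²/lc²)`, whose 1D spectral density is
  ∝ `k² exp(-k² lc²/4)`.  Line processes are synthesized spectrally on a 1D
  grid at half the voxel pitch and linearly interpolated at the voxel
  projections.

The spectral route is the default because its discrete statistics are exact
by construction; turning bands is retained because it is the classical
construction for such models, and the two are asserted equivalent (ensemble
correlation curves within ±0.05 of each other and of the analytic target up
to 2·lc).

Seeding: one integer seed fully determines a field; replicate `k` of a sweep
combination uses `base_seed + k`.

## Far-field solver

The reference solver is a **first-Born** (single weak scattering) solver:
for an x-polarized plane wave at vacuum wavelength λ = 800 nm propagating
along +z in a medium of index `n_out`, the far-field intensity is

    I(θ, φ) ∝ |F̂(q(θ, φ))|² · (1 − sin²θ cos²φ),

where `F̂` is the 3D Fourier transform of the scattering potential
`k₀² [n(x)² − n_out²]` (k₀ = 2π/λ), evaluated on the Ewald sphere
`q = k(ŝ − ẑ)` with `k = 2π n_out / λ` and
`ŝ = (sinθ cosφ, sinθ sinφ, cosθ)`; the last factor is the dipole
polarization factor for x-polarized incidence.  Patterns are sampled on the
full 1° grid, 181 × 361 values; the φ grid deliberately carries the
duplicated φ = 360 column, which texture analysis drops before counting.

Numerically the potential is zero-padded (factor ≥ 2, default 2), FFT'd
with the nucleus center rolled to the FFT origin (so the transform is
phase-centered and smooth), and interpolated at the Ewald q-points with a
cubic spline (`scipy.ndimage.map_coordinates`, order 3; order and pad factor
configurable).  Against the closed-form sphere form factor
`3[sin(qR) − qR cos(qR)]/(qR)³` the default settings give ~0.25% relative
RMS amplitude error away from diffraction nulls.  Linear interpolation at
pad 2 is an order of magnitude worse (~7%) because the form-factor fringes
in q are only ~2 grid samples wide; the cubic default is what makes the
2%-level oracle hold at tractable FFT sizes.

A full **Mie series** (`mie_reference`) serves as an independent oracle for
homogeneous spheres: coefficients `a_n, b_n` from Riccati–Bessel functions,
amplitudes `S1, S2` via the π/τ recursions, azimuthal assembly
`I ∝ |S2 cosφ|² + |S1 sinφ|²`.  Its internal consistency is checked by
Gauss–Legendre quadrature of `|S1|² + |S2|²` against the efficiency-series
cross-section (agreement ~1e-10 relative); Gauss–Legendre nodes are used
because the forward lobe of a size-parameter-~43 sphere is about one degree
wide and the fixed 1° grid undersamples it.

**What Born does and does not deliver.**  A rigorous time-domain solve of
Maxwell's equations is an established method and not this package's
contribution; at the index contrast of a nucleus in cytoplasm
(n − n_out ≈ 0.04 over ~8 µm) the single-scattering approximation is
quantitatively imperfect.  Absolute pattern intensities are therefore *not*
comparable to rigorous solvers, and all downstream conclusions rest on
directional trends and self-normalized texture features, which is also why
the solver backend is a registry: an external rigorous solver emitting the
same grid slots in without touching the analysis.

## Texture features

Per pattern: `L = log10 I`, with intensities floored at 1e-12 of the pattern
maximum before the logarithm (a numerical guard; far-field nulls would
otherwise give −∞).  A full-scale contrast stretch maps `L` to integers
0–255; gray levels are `⌊Ĩ/32⌋ ∈ {0..7}`.  Co-occurrence matrices count
*ordered* neighbor pairs at offset exactly +1 along θ or φ, both pixels
inside the (inclusive) angular range, with no wrap-around in either
direction and the duplicate φ = 360 column removed.  Haralick contrast is
`Σ |i−j|² p(i,j)` of the normalized matrix; the contrast ratio is
`contrast_φ / contrast_θ` and is reported as *undefined* (an explicit
exception, never an infinity) when the polar contrast vanishes, as for a
constant pattern.

Angular ranges: small-angle θ 0–40°, side 40–140°, high-angle 140–180°, all
over the full azimuth, endpoints inclusive (adjacent ranges share their
boundary row).  Mean intensity is the arithmetic mean of `log10(I/Io)` over
the range on the deduplicated grid; the reference intensity `Io` defaults
to 1 in solver units, since within-study feature comparisons need only a
consistent normalization, not absolute calibration.

**Stretch scope.**  The stretch is recomputed inside each angular range by
default (`stretch_scope="per_range"`; a single global stretch is available
via the switch).  The reason is dynamic range: a pattern spans six or more
decades between the forward peak and the side band, so under a global
stretch the side band occupies only a few of the 256 levels — and its share
*shrinks* as growing `δn` raises large-angle intensities, largely cancelling
the texture response the features exist to measure.  Stretching within the
analyzed range keeps the 8-level quantization matched to the local dynamic
range; with it, side-range azimuthal contrast rises monotonically with `δn`
for every replicate seed, while a global stretch leaves it flat.

Replicates: three models per parameter combination (seeds
`base_seed + {0,1,2}`); features are reported as the replicate mean with
standard error `sample std / √k` (undefined, reported as NaN, for `k = 1`).

## Correlation length from images

Feulgen-thionin staining is stoichiometric for DNA, so the optical density
(OD) of an image pixel tracks DNA concentration, and refractive index is
linear in concentration: the spatial correlation of OD fluctuations proxies
the correlation of index fluctuations.  The estimator:

1. per-row and per-column autocorrelation of a rectangular ROI, using the
   biased (divide-by-N), mean-removed, zero-lag-normalized estimator —
   stable for short lines; the series' own sample mean is subtracted;
2. one-parameter nonlinear least-squares fit of `exp(-r²/lc²)` (amplitude
   fixed at 1, lag 0 included) over the leading lags up to — exclusive —
   the first autocorrelation value below 0.05 or below zero.  The model is
   non-negative, so the noise-dominated tail must be excluded; the 0.05
   cutoff is config-exposed;
3. acceptance filter: at least 4 fitted points and R² > 0.95 (R² computed
   against the fitted points);
4. the ROI estimate is the mean over accepted line fits; the nucleus
   estimate is the mean over three ROIs (an ROI with no accepted fit is
   dropped and flagged).  Micron conversion is `lc_µm = lc_px × 0.34` at the
   default 20×/0.75 NA, 600 nm imaging geometry; reported values are rounded
   to two decimals.

**Known estimator bias near the sampling limit.**  At `lc` comparable to
the 0.34 µm pixel pitch the protocol is intrinsically biased upward: for
`lc = 0.4` µm the true correlation at lag 3 is ~1.5e-3, far below the usable
cutoff, so a line reaches the 4-point minimum only when its empirical
autocorrelation fluctuates high — a selection that retains slow-decaying
lines.  Simulations with the exact process mean and lines up to 32 px show
the ~+25% bias is irreducible within the stated filter rules.  Estimates at
`lc ≥ 0.7` µm are accurate to better than ±10% under the synthetic
conditions below, and the ranking of nuclei by `lc` is preserved across the
whole range.

## Synthetic data

`synthetic_data.make_nucleus_image` emulates the image population the
estimator targets: OD = `od_mean + od_std · g2D` inside an elliptical
nuclear mask (exact `background_od` outside), where `g2D` is a 2D Gaussian
field with correlation `exp(-r²/lc_true²)`.  The field is synthesized on a
grid fine enough for the correlation length (≥ 4 samples per `lc`) and
point-sampled at the 0.34 µm pitch — what an idealized imaging system does
to a continuous specimen.  Defaults: 104 × 104 px images, nuclear semi-axes
13.5 × 10.0 µm (the larger dysplastic nuclei), `od_std/od_mean = 0.25`
(clearly visible chromatin-like texture), three disjoint 24 × 24 px ROIs
stacked along the major axis.  ROI size matters: per-line autocorrelations
from short lines are noisy and negatively biased by mean removal, and 24-px
lines are the longest that fit three disjoint ROIs inside a realistic mask.

What the synthetic images deliberately lack: optical blur (the PSF at
0.75 NA is comparable to the pixel), detector noise, staining
heterogeneity, and non-elliptical nuclear boundaries.  Passing recovery
tests therefore validates the estimator's statistical protocol, not its
robustness to real imaging physics.

`make_fixture_suite` materializes the full fixture tree (truth-labelled
images, homogeneous reference spheres, default stochastic model trios) with
a machine-readable manifest; regeneration from the same master seed is
bit-identical (HDF5 timestamps disabled).

## Sweeps, trends, invariance

`experiments.run_sweep` chains models → patterns → features for a canonical
grid and aggregates replicates into a tidy table; output CSVs are
byte-stable for a fixed config.  The default sweep uses the reduced grids
`lc ∈ {0.5, 0.7, 0.9}` µm and `δn ∈ {0.010, 0.020, 0.030}` with three
replicates at 0.1 µm pitch — problem sizes chosen so a full trend analysis
runs in tens of seconds on one CPU; the full seven-point grids sit behind
`full_grid=True`.

`trend_check` reports the Spearman sign and strict monotonicity of a
replicate-mean feature series.  `invariance_check` quantifies selectivity:
the max−min dispersion of side-range contrast ratio across size/index
variations (at `lc = 0.7`, `δn = 0.020`) divided by its change between
`lc = 0.4` and `lc = 1.0`.  With the Born backend this ratio comes out
around 0.25 — the feature moves four times further over the physiological
`lc` range than under any realistic change of nuclear size or mean index.

## Numerical choices and degenerate inputs

* Correlation refusals: spacing > lc/2 (unresolvable correlation),
  non-positive lc, fields with zero variance.
* Autocorrelation of numerically constant lines is refused via a relative
  variance guard (residuals at the level of mean-subtraction round-off).
* Constant patterns: stretch maps to all zeros and is flagged degenerate;
  both contrasts are 0; the contrast ratio raises
  `DegeneratePatternError`.
* Backend outputs are validated on construction: exact 181 × 361 grid,
  finite, non-negative.
* HDF5 round-trips are lossless and refuse files with missing metadata,
  naming the absent fields.

## Limitations

* The Born solver is perturbative; absolute intensities and fine pattern
  detail differ from rigorous electromagnetic solutions, and only trends
  and self-normalized features should be interpreted.
* Only the Gaussian correlation family is implemented; power-law or
  exponential families (e.g. the Whittle–Matérn family) are out of scope.
* The ellipsoid orientation is fixed to the lab axes; no rotations or
  multi-cell geometries.
* The image estimator inherits the upward small-`lc` bias of its acceptance
  protocol near the pixel pitch (see above), and the synthetic validation
  does not exercise PSF blur or sensor noise.
* Haralick features beyond contrast (energy, homogeneity, correlation,
  entropy) are not computed; the GLCM machinery is generic and extensible.
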