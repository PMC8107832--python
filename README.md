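# nucscatter

Tools for asking a precise biophotonics question: **can optical scattering
measurements sense the *internal* refractive-index structure of a cell
nucleus, independently of its overall size and mean index?**

Chromatin reorganisation is a hallmark of precancer progression, and it
manifests as changes in the statistics of subnuclear refractive-index
fluctuations — their correlation length `lc` and their extent `δn`.
Conventional scattering intensity features are dominated by gross morphology
(radius `R`, semi-axes `Sx, Sy, Sz`) and mean index `n`, which masks those
internal changes.  This package implements a simulation-and-analysis
pipeline that isolates them:

1. **Stochastic nuclear models** (`nuclear_models`, `random_fields`) —
   spheres or ellipsoids of mean index `n` in homogeneous cytoplasm `n_out`,
   with an internal Gaussian random field whose two-point correlation is

   `C(r) = exp(-r² / lc²)`

   scaled so that `δn` is the standard deviation of the index fluctuations.
   Fields are synthesized spectrally (FFT filtering of white noise) or by
   the turning-bands method; both are tested against the analytic target.

2. **Azimuth-resolved far-field patterns** (`scattering`) — the intensity
   `I(θ, φ)` on the full 1° grid (θ ∈ {0..180}, φ ∈ {0..360}) for an
   x-polarized 800 nm plane wave travelling along +z.  The reference solver
   is a first-Born FFT solver (3D FFT of the scattering potential sampled on
   the Ewald sphere, times the dipole polarization factor `1 − sin²θ cos²φ`),
   validated against the closed-form sphere form factor and a full Mie
   series oracle.  Rigorous solvers (e.g. FDTD) can be plugged in through a
   backend registry as long as they emit the same 181 × 361 grid.

3. **Texture features** (`features`) — each pattern's `log10 I` is
   contrast-stretched to 0–255, quantized to 8 gray levels, and reduced to
   gray-level co-occurrence matrices with an offset of one along θ or φ.
   The Haralick contrast `Σ |i−j|² p(i,j)` along φ (azimuthal contrast),
   along θ (polar contrast), and their ratio `contrast_φ/θ` are computed per
   angular range (small-angle θ ≤ 40°, side 40–140°, high-angle ≥ 140°),
   with three stochastic replicates aggregated as mean ± standard error.

4. **Correlation length from images** (`image_lc`) — the companion
   estimator for stained-nucleus optical-density images (0.34 µm/pixel):
   per-row/column autocorrelation of rectangular ROIs, one-parameter fits of
   `exp(-r²/lc²)`, acceptance filters (≥ 4 points, R² > 0.95), ROI and
   nucleus averaging.

5. **Sweeps and verdicts** (`experiments`, `synthetic_data`) — parameter
   sweeps over the canonical model grids with deterministic seeding, trend
   (monotonicity) checks, and the size/index-invariance check; plus
   truth-labelled synthetic fixtures for everything, generated locally.

The headline behaviour the pipeline reproduces: **side-scatter azimuthal
contrast and contrast ratio fall monotonically with `lc` and rise
monotonically with `δn`, while staying nearly unchanged under realistic
variations of nuclear size and mean index** — the signature that makes them
candidate probes of chromatin structure.

## Worked example

```python
from nucscatter import (NuclearModelSpec, build_model, born_far_field,
                        feature_set, PlaneWaveConfig)

spec = NuclearModelSpec(shape_kind="sphere", R=4.0, n=1.40, n_out=1.36,
                        lc=0.7, delta_n=0.020, spacing=0.1, seed=0)
volume = build_model(spec)                  # 3D refractive-index grid
pattern = born_far_field(volume, PlaneWaveConfig())   # I(theta, phi), 181 x 361
features = feature_set(pattern)
side = features.per_range["side"]
print(f"mean log10(I/Io) over side range : {side['mean_intensity']:.3f}")
print(f"polar contrast (theta offset)    : {side['contrast_theta']:.4f}")
print(f"azimuthal contrast (phi offset)  : {side['contrast_phi']:.4f}")
print(f"contrast ratio phi/theta         : {side['contrast_ratio']:.4f}")
```

prints

```
mean log10(I/Io) over side range : -0.231
polar contrast (theta offset)    : 0.2858
azimuthal contrast (phi offset)  : 0.0569
contrast ratio phi/theta         : 0.1992
```

The side-range azimuthal contrast (0.057) measures how often and how
strongly the stretched pattern jumps between gray levels as φ advances by
1°; dividing by the polar contrast (0.286) normalizes away fringe structure
driven by overall nuclear morphology, leaving the ratio (0.199) as the
feature that tracks internal structure.  Re-running with `lc=0.9` lowers the
ratio; with `delta_n=0.030` it rises.

A command-line interface mirrors the pipeline:

```bash
nucscatter build-models --table table1_dense --mode lc_sweep --out models/ --seed 0
nucscatter scatter --models models/ --backend born --out patterns/ --render
nucscatter features --patterns patterns/ --out features.csv
nucscatter extract-lc --image nucleus.tif --pixel-um 0.34 \
    --roi 16,40,40,64 --roi 40,40,64,64 --roi 64,40,88,64
nucscatter make-fixtures --out fixtures/ --seed 0
nucscatter sweep --config sweep.yaml --out sweepout/
```

## Documentation

`docs/methods.md` describes the models, estimators, numerical choices and
known limitations in detail.
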