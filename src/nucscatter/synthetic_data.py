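"""Synthetic fixtures: nuclear OD images with known lc, and reference model batches.

``make_nucleus_image`` emulates the quantitative-histopathology image
population the lc estimator is designed for: optical-density fluctuations
with a known Gaussian correlation length inside an elliptical nuclear mask,
sampled at 0.34 um/pixel.  The OD field is synthesized on a grid fine enough
to resolve the correlation length (at least 4 samples per lc) and then
point-sampled at the pixel pitch, which is what an idealized imaging system
does to a continuous specimen; optical blur (PSF) is deliberately not
modelled.

``make_fixture_suite`` materializes every fixture the pipeline needs without
any network access: truth-labelled images for estimator validation,
homogeneous spheres for solver oracles, and the default stochastic model
trios for the three model families.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from nucscatter.random_fields import CorrelationSpec, generate_grf_2d
from nucscatter.nuclear_models import NuclearModelSpec, build_model, save_model
from nucscatter.image_lc import NuclearImage, DEFAULT_PIXEL_UM

__all__ = ["SyntheticImageSpec", "make_nucleus_image", "make_fixture_suite"]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic nuclear OD image.

    ``nucleus_axes`` are the semi-axes (um) of the elliptical nuclear mask
    along image rows and columns.  ``od_std / od_mean`` defaults to 0.25,
    giving clearly visible chromatin-like texture against the mean density.
    """

    lc_true: float
    pixel_size: float = DEFAULT_PIXEL_UM
    image_shape: tuple[int, int] = (104, 104)
    nucleus_axes: tuple[float, float] = (13.5, 10.0)
    od_mean: float = 1.0
    od_std: float = 0.25
    background_od: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lc_true > 0:
            raise ValueError("lc_true must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


def _elliptical_mask(shape: tuple[int, int], pixel_size: float,
                     axes_um: tuple[float, float]) -> np.ndarray:
    cr, cc = ((n - 1) / 2.0 for n in shape)
    r = (np.arange(shape[0]) - cr) * pixel_size / axes_um[0]
    c = (np.arange(shape[1]) - cc) * pixel_size / axes_um[1]
    return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0


def default_rois(spec: SyntheticImageSpec, roi_size: int = 24) -> list[tuple[int, int, int, int]]:
    """Three disjoint ROI rectangles stacked along the nucleus major axis.

    The stack runs along image rows (the longer nuclear semi-axis of the
    default geometry); bounds are half-open.  Large ROIs are preferred
    because the per-line autocorrelation estimates, and hence the Gaussian
    fits, stabilize with line length.
    """
    nr, nc = spec.image_shape
    r_mid = nr // 2
    c0 = nc // 2 - roi_size // 2
    return [
        (r_mid - 3 * roi_size // 2 + k * roi_size, c0,
         r_mid - 3 * roi_size // 2 + (k + 1) * roi_size, c0 + roi_size)
        for k in range(3)
    ]


def make_nucleus_image(spec: SyntheticImageSpec, roi_size: int = 24
                       ) -> tuple[NuclearImage, dict]:
    """Generate a synthetic nuclear image plus its machine-readable truth record.

    Inside the elliptical mask, OD = od_mean + od_std * g where g is a 2D
    Gaussian random field with correlation exp(-r^2/lc_true^2); outside, OD
    is exactly ``background_od``.  The truth record carries ``lc_true_um``
    and three disjoint centered ROI rectangles of ``roi_size`` pixels.

    Raises if the nuclear mask cannot contain the three ROIs.
    """
    if roi_size < 8:
        raise ValueError("ROIs must be at least 8x8 pixels")
    mask = _elliptical_mask(spec.image_shape, spec.pixel_size, spec.nucleus_axes)
    rois = default_rois(spec, roi_size)
    for r0, c0, r1, c1 in rois:
        if r0 < 0 or c0 < 0 or r1 > spec.image_shape[0] or c1 > spec.image_shape[1]:
            raise ValueError("image too small for three disjoint ROIs")
        if not mask[r0:r1, c0:c1].all():
            raise ValueError("nuclear mask too small to contain the three ROIs")

    # Synthesize on a finer grid (>= 4 samples per lc), then point-sample at
    # the pixel pitch; point sampling preserves the two-point correlation.
    k = max(1, int(np.ceil(4.0 * spec.pixel_size / spec.lc_true)))
    fine_shape = tuple(n * k for n in spec.image_shape)
    g_fine = generate_grf_2d(fine_shape, spec.pixel_size / k,
                             CorrelationSpec(lc=spec.lc_true), seed=spec.seed)
    g = g_fine.values[::k, ::k]

    od = np.full(spec.image_shape, spec.background_od, dtype=float)
    od[mask] = spec.od_mean + spec.od_std * g[mask]
    image = NuclearImage(od=od, pixel_size=spec.pixel_size, mask=mask)
    truth = {
        "lc_true_um": spec.lc_true,
        "pixel_size_um": spec.pixel_size,
        "rois": [list(r) for r in rois],
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
    }
    return image, truth


def make_fixture_suite(out_dir, master_seed: int = 0, n_image_seeds: int = 20,
                       image_lcs: tuple[float, ...] = (0.4, 0.7, 1.0),
                       model_spacing: float = 0.1) -> dict:
    """Write the full fixture tree and return its manifest.

    Contents: (a) truth-labelled OD images at each lc in ``image_lcs`` for
    ``n_image_seeds`` seeds; (b) homogeneous spheres of radius 3.5/4.0/4.5 um;
    (c) the default stochastic trios (dense sphere, index-inverted sphere,
    ellipsoid) at lc=0.7 um, delta_n=0.020, three seeds each.  A
    ``manifest.json`` lists every file with its ground truth.  Regeneration
    with the same master seed is bit-identical.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": master_seed, "images": [], "models": []}

    for i, lc in enumerate(image_lcs):
        for s in range(n_image_seeds):
            spec = SyntheticImageSpec(lc_true=lc, seed=master_seed + 1000 * i + s)
            image, truth = make_nucleus_image(spec)
            name = f"images/lc{lc:.2f}_seed{spec.seed}.tif"
            tifffile.imwrite(out / name, image.od.astype(np.float32))
            manifest["images"].append({"path": name, **truth})

    for R in (3.5, 4.0, 4.5):
        spec = NuclearModelSpec(shape_kind="sphere", R=R, n=1.40, n_out=1.36,
                                lc=0.7, delta_n=0.0, spacing=model_spacing)
        name = f"models/homog_sphere_R{R:.1f}.h5"
        save_model(build_model(spec), out / name)
        manifest["models"].append({"path": name, "spec": dataclasses.asdict(spec),
                                   "kind": "homogeneous_sphere"})

    trios = {
        "sphere_dense": dict(shape_kind="sphere", R=4.0, n=1.40, n_out=1.36),
        "sphere_inverted": dict(shape_kind="sphere", R=4.0, n=1.36, n_out=1.40),
        "ellipsoid": dict(shape_kind="ellipsoid", Sx=3.0, Sy=5.0, Sz=4.0,
                          n=1.40, n_out=1.36),
    }
    for label, geom in trios.items():
        for rep in range(3):
            spec = NuclearModelSpec(lc=0.7, delta_n=0.020, spacing=model_spacing,
                                    seed=master_seed + rep, **geom)
            name = f"models/{label}_rep{rep}.h5"
            save_model(build_model(spec), out / name)
            manifest["models"].append({"path": name, "spec": dataclasses.asdict(spec),
                                       "kind": "stochastic_default"})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
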