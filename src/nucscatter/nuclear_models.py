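"""Spherical and ellipsoidal nuclear refractive-index models with stochastic interiors.

A model is a nucleus of mean refractive index ``n`` embedded in homogeneous
cytoplasm of index ``n_out``.  Inside the nuclear surface the index is

    n(x) = n + delta_n * g(x)

where ``g`` is a zero-mean, unit-variance Gaussian random field with
correlation exp(-r^2/lc^2) (see :mod:`nucscatter.random_fields`) and
``delta_n`` is the extent of the refractive-index fluctuations, interpreted as
the population standard deviation of the un-clipped fluctuation field.  The
field is re-centered over the nuclear mask so that the sample mean of n(x)
inside the nucleus equals ``n`` essentially exactly, which keeps size and
mean-index sweeps free of finite-sample drift.

``parameter_grid`` enumerates the canonical sweep grids for the three model
families (dense sphere, index-inverted sphere, dense ellipsoid).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import h5py

from nucscatter.random_fields import CorrelationSpec, generate_grf

__all__ = [
    "NuclearModelSpec",
    "RefractiveIndexVolume",
    "build_model",
    "parameter_grid",
    "save_model",
    "load_model",
    "SPHERE_DENSE_DEFAULTS",
    "SPHERE_INVERTED_DEFAULTS",
    "ELLIPSOID_DEFAULTS",
]

# Canonical parameter values for the three model families.  "Defaults" are the
# values held fixed while another parameter is swept.
SPHERE_DENSE_VALUES = {
    "R": (3.5, 4.0, 4.5),
    "n": (1.39, 1.40, 1.41),
    "n_out": (1.36,),
    "lc": (0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    "delta_n": (0.005, 0.010, 0.015, 0.020, 0.025, 0.030, 0.035),
}
SPHERE_INVERTED_VALUES = {
    **SPHERE_DENSE_VALUES,
    "n": (1.35, 1.36, 1.37),
    "n_out": (1.40,),
}
ELLIPSOID_VALUES = {
    "Sx": (2.5, 3.0, 3.5),
    "Sy": (4.5, 5.0, 5.5),
    "Sz": (3.5, 4.0, 4.5),
    "n": (1.39, 1.40, 1.41),
    "n_out": (1.36,),
    "lc": SPHERE_DENSE_VALUES["lc"],
    "delta_n": SPHERE_DENSE_VALUES["delta_n"],
}

SPHERE_DENSE_DEFAULTS = {"R": 4.0, "n": 1.40, "n_out": 1.36, "lc": 0.7, "delta_n": 0.020}
SPHERE_INVERTED_DEFAULTS = {"R": 4.0, "n": 1.36, "n_out": 1.40, "lc": 0.7, "delta_n": 0.020}
ELLIPSOID_DEFAULTS = {
    "Sx": 3.0, "Sy": 5.0, "Sz": 4.0, "n": 1.40, "n_out": 1.36, "lc": 0.7, "delta_n": 0.020,
}


@dataclass(frozen=True)
class NuclearModelSpec:
    """Full recipe for one stochastic nuclear model.

    Lengths in micrometres; refractive indices dimensionless.  A sphere uses
    ``R``; an ellipsoid uses semiaxes ``Sx, Sy, Sz`` aligned with the lab
    x, y, z axes (the incident wave propagates along +z).
    """

    shape_kind: str
    n: float
    n_out: float
    lc: float
    delta_n: float
    spacing: float = 0.05
    seed: int = 0
    R: float | None = None
    Sx: float | None = None
    Sy: float | None = None
    Sz: float | None = None

    def __post_init__(self) -> None:
        if self.shape_kind not in ("sphere", "ellipsoid"):
            raise ValueError(f"shape_kind must be 'sphere' or 'ellipsoid', got {self.shape_kind!r}")
        if self.shape_kind == "sphere":
            if self.R is None or not self.R > 0:
                raise ValueError("sphere requires a positive radius R")
        else:
            if any(s is None or not s > 0 for s in (self.Sx, self.Sy, self.Sz)):
                raise ValueError("ellipsoid requires positive semiaxes Sx, Sy, Sz")
        for name in ("lc", "spacing"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n", "n_out"):
            if not 1.0 < getattr(self, name) < 2.0:
                raise ValueError(f"{name} must lie in (1, 2)")
        if self.delta_n < 0:
            raise ValueError("delta_n must be non-negative")

    @property
    def semiaxes(self) -> tuple[float, float, float]:
        if self.shape_kind == "sphere":
            return (self.R, self.R, self.R)
        return (self.Sx, self.Sy, self.Sz)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NuclearModelSpec":
        return cls(**json.loads(text))


@dataclass
class RefractiveIndexVolume:
    """3D refractive-index grid plus provenance.

    ``origin`` is the (fractional) voxel coordinate of the nucleus center;
    ``realized_std`` records the sample standard deviation of the fluctuation
    actually realized inside the mask (in refractive-index units).
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, float, float]
    spec: NuclearModelSpec
    realized_std: float = 0.0

    @property
    def mask(self) -> np.ndarray:
        """Boolean nuclear mask from the analytic surface (voxel-center rule)."""
        return _ellipsoid_mask(self.values.shape, self.spacing, self.origin, self.spec.semiaxes)

    @property
    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical axis coordinates (um) relative to the nucleus center."""
        return tuple(
            self.spacing * (np.arange(n) - o) for n, o in zip(self.values.shape, self.origin)
        )


def _ellipsoid_mask(shape, spacing, origin, semiaxes) -> np.ndarray:
    ax = [spacing * (np.arange(n) - o) / s for n, o, s in zip(shape, origin, semiaxes)]
    return (
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    ) <= 1.0


def build_model(spec: NuclearModelSpec, method: str = "spectral",
                margin_voxels: int = 3, n_lines: int = 1000) -> RefractiveIndexVolume:
    """Construct the refractive-index volume for a model spec.

    The grid spans the nucleus plus ``margin_voxels`` of cytoplasm on every
    side.  Inside the mask the fluctuation field is re-centered so the masked
    sample mean equals ``spec.n`` exactly; outside, voxels are ``spec.n_out``.

    Raises
    ------
    ValueError
        If the fluctuations would push any voxel index to 1 or below (an
        unphysical medium), or for an invalid margin.
    """
    if margin_voxels < 2:
        raise ValueError("need at least 2 voxels of cytoplasmic margin")
    semiaxes = spec.semiaxes
    h = spec.spacing
    shape = tuple(2 * (int(np.ceil(s / h)) + margin_voxels) + 1 for s in semiaxes)
    origin = tuple((n - 1) / 2.0 for n in shape)
    mask = _ellipsoid_mask(shape, h, origin, semiaxes)

    values = np.full(shape, spec.n_out, dtype=float)
    realized_std = 0.0
    if spec.delta_n > 0:
        grf = generate_grf(shape, h, CorrelationSpec(lc=spec.lc), seed=spec.seed,
                           method=method, n_lines=n_lines)
        g = grf.values[mask]
        fluct = spec.delta_n * (g - g.mean())
        inside = spec.n + fluct
        if inside.min() <= 1.0:
            raise ValueError(
                f"delta_n={spec.delta_n} drives the minimum index to {inside.min():.4f} <= 1; "
                "unphysical model refused"
            )
        values[mask] = inside
        realized_std = float(fluct.std())
    else:
        values[mask] = spec.n
    return RefractiveIndexVolume(values=values, spacing=h, origin=origin, spec=spec,
                                 realized_std=realized_std)


_TABLES = {
    "table1_dense": ("sphere", SPHERE_DENSE_VALUES, SPHERE_DENSE_DEFAULTS),
    "table1_inverted": ("sphere", SPHERE_INVERTED_VALUES, SPHERE_INVERTED_DEFAULTS),
    "table2": ("ellipsoid", ELLIPSOID_VALUES, ELLIPSOID_DEFAULTS),
}


def parameter_grid(table: str, mode: str, spacing: float = 0.05,
                   base_seed: int = 0) -> list[NuclearModelSpec]:
    """Enumerate model specs for a canonical sweep.

    Parameters
    ----------
    table : str
        ``table1_dense`` (sphere, nucleus denser than cytoplasm),
        ``table1_inverted`` (sphere, index-inverted) or ``table2`` (ellipsoid).
    mode : str
        ``lc_sweep`` — hold size and indices at defaults, delta_n at 0.020,
        sweep lc over 0.4..1.0;
        ``dn_sweep`` — hold lc at 0.7, sweep delta_n over 0.005..0.035;
        ``size_index_sweep`` — hold lc=0.7, delta_n=0.020, vary the size
        parameter(s) and mean index one at a time off the defaults
        (duplicated all-default combination included once).
    """
    try:
        shape_kind, values, defaults = _TABLES[table]
    except KeyError:
        raise ValueError(f"unknown table {table!r}; expected one of {sorted(_TABLES)}") from None

    def make(**overrides) -> NuclearModelSpec:
        params = dict(defaults)
        params.update(overrides)
        return NuclearModelSpec(shape_kind=shape_kind, spacing=spacing, seed=base_seed, **params)

    if mode == "lc_sweep":
        return [make(lc=lc) for lc in values["lc"]]
    if mode == "dn_sweep":
        return [make(delta_n=dn) for dn in values["delta_n"]]
    if mode == "size_index_sweep":
        size_params = ("R",) if shape_kind == "sphere" else ("Sx", "Sy", "Sz")
        specs: list[NuclearModelSpec] = []
        for p in size_params + ("n",):
            for v in values[p]:
                s = make(**{p: v})
                if s not in specs:
                    specs.append(s)
        return specs
    raise ValueError(
        f"unknown mode {mode!r}; expected 'lc_sweep', 'dn_sweep' or 'size_index_sweep'"
    )


def save_model(volume: RefractiveIndexVolume, path) -> None:
    """Write a model to HDF5 (dataset ``/index_volume`` + metadata attrs)."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps file bytes reproducible across runs
        d = f.create_dataset("index_volume", data=volume.values, track_times=False)
        d.attrs["spacing_um"] = volume.spacing
        d.attrs["origin"] = np.asarray(volume.origin)
        d.attrs["spec"] = volume.spec.to_json()
        d.attrs["realized_std"] = volume.realized_std


def load_model(path) -> RefractiveIndexVolume:
    """Read a model written by :func:`save_model`; refuses files with missing metadata."""
    with h5py.File(path, "r") as f:
        if "index_volume" not in f:
            raise ValueError("not a model file: missing dataset 'index_volume'")
        d = f["index_volume"]
        missing = [k for k in ("spacing_um", "origin", "spec") if k not in d.attrs]
        if missing:
            raise ValueError(f"model file missing required metadata: {', '.join(missing)}")
        return RefractiveIndexVolume(
            values=d[...],
            spacing=float(d.attrs["spacing_um"]),
            origin=tuple(float(v) for v in d.attrs["origin"]),
            spec=NuclearModelSpec.from_json(d.attrs["spec"]),
            realized_std=float(d.attrs.get("realized_std", 0.0)),
        )
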