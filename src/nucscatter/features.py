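"""Intensity and GLCM texture features of 2D scattering patterns.

The feature set mirrors a standard Haralick texture analysis applied to the
log-scaled pattern:

1. mean log-intensity  <log10[I(theta, phi) / Io]>  over an angular range,
   with Io a reference intensity (default 1 in solver units — within-study
   comparisons only need consistency, not absolute calibration);
2. a full-scale contrast stretch of log10[I] to integer values 0..255 over
   the whole pattern;
3. gray-level co-occurrence matrices at 8 gray levels (quantization
   floor(I_tilde / 32)) with an ordered offset of exactly +1 along theta
   (polar) or phi (azimuthal), pairs restricted to the angular range;
4. Haralick contrast  sum |i - j|^2 p(i, j)  of each normalized GLCM, and the
   contrast ratio contrast_phi / contrast_theta.

The three canonical angular ranges are small-angle (theta 0-40 deg), side
(40-140 deg) and high-angle (140-180 deg), each over the full azimuth; range
endpoints are inclusive on both sides, so adjacent ranges share a boundary
row.  The duplicated phi = 360 column of the pattern grid is dropped before
any pixel counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nucscatter.scattering import ScatteringPattern

__all__ = [
    "AngularRange",
    "DEFAULT_RANGES",
    "StretchedPattern",
    "GLCM",
    "FeatureSet",
    "DegeneratePatternError",
    "FEATURE_NAMES",
    "mean_log_intensity",
    "contrast_stretch",
    "glcm",
    "normalize_glcm",
    "haralick_contrast",
    "feature_set",
    "aggregate_replicates",
]

N_GRAY = 8
_FLOOR_REL = 1e-12  # intensities below this fraction of the max are floored before log10

FEATURE_NAMES = ("mean_intensity", "contrast_theta", "contrast_phi", "contrast_ratio")


class DegeneratePatternError(ValueError):
    """Raised when a pattern is too degenerate for a feature to be defined."""


@dataclass(frozen=True)
class AngularRange:
    """Inclusive angular window [theta_min, theta_max] x [phi_min, phi_max], degrees."""

    name: str
    theta_min: int
    theta_max: int
    phi_min: int = 0
    phi_max: int = 360

    def __post_init__(self) -> None:
        if not (0 <= self.theta_min < self.theta_max <= 180):
            raise ValueError("require 0 <= theta_min < theta_max <= 180")
        if not (0 <= self.phi_min < self.phi_max <= 360):
            raise ValueError("require 0 <= phi_min < phi_max <= 360")


DEFAULT_RANGES = (
    AngularRange("small_angle", 0, 40),
    AngularRange("side", 40, 140),
    AngularRange("high_angle", 140, 180),
)


@dataclass
class StretchedPattern:
    """Full-scale contrast-stretched log-pattern, integer values in 0..255."""

    values: np.ndarray          # (181, 361) integers
    source_min: float           # min of log10 intensity before stretching
    source_max: float
    degenerate: bool = False    # constant source pattern

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < 0 or v.max() > 255:
            raise ValueError("stretched values must lie in [0, 255]")


@dataclass
class GLCM:
    """Gray-level co-occurrence counts (8 x 8, ordered pairs, offset +1)."""

    counts: np.ndarray
    direction: str              # "theta" or "phi"
    range: AngularRange

    def __post_init__(self) -> None:
        if self.counts.shape != (N_GRAY, N_GRAY):
            raise ValueError("GLCM must be 8 x 8")
        if np.any(self.counts < 0):
            raise ValueError("GLCM counts must be non-negative")


@dataclass
class FeatureSet:
    """All features of one pattern: per-range mean intensity and contrasts."""

    per_range: dict             # range name -> {feature name -> value}
    replicate_id: int = 0
    provenance: dict = field(default_factory=dict)


def _log_intensity(intensity: np.ndarray) -> np.ndarray:
    """log10 of the pattern with tiny values floored relative to the max."""
    peak = intensity.max()
    if peak <= 0:
        raise DegeneratePatternError("pattern has no positive intensity")
    return np.log10(np.maximum(intensity, _FLOOR_REL * peak))


def _dedup(values: np.ndarray) -> np.ndarray:
    """Drop the duplicated phi=360 column."""
    return values[:, :-1]


def _range_slices(rng: AngularRange) -> tuple[slice, slice]:
    """Row/column slices of the (inclusive) range on the deduplicated grid."""
    phi_hi = min(rng.phi_max, 359)
    return slice(rng.theta_min, rng.theta_max + 1), slice(rng.phi_min, phi_hi + 1)


def mean_log_intensity(pattern: ScatteringPattern, rng: AngularRange, Io: float = 1.0) -> float:
    """Arithmetic mean of log10(I/Io) over the range, on the deduplicated phi grid."""
    if not Io > 0:
        raise ValueError("reference intensity Io must be positive")
    logI = _dedup(_log_intensity(pattern.intensity))
    rs, cs = _range_slices(rng)
    return float(np.mean(logI[rs, cs]) - np.log10(Io))


def contrast_stretch(pattern: ScatteringPattern) -> StretchedPattern:
    """Full-scale contrast stretch of log10(I) over the whole 181 x 361 pattern.

    I_tilde = round(255 (L - Lmin) / (Lmax - Lmin)); a constant pattern maps
    to all zeros and is flagged degenerate.
    """
    L = _log_intensity(pattern.intensity)
    lo, hi = float(L.min()), float(L.max())
    if hi == lo:
        return StretchedPattern(values=np.zeros_like(L, dtype=np.int64),
                                source_min=lo, source_max=hi, degenerate=True)
    vals = np.rint(255.0 * (L - lo) / (hi - lo)).astype(np.int64)
    return StretchedPattern(values=vals, source_min=lo, source_max=hi)


def quantize(stretched: StretchedPattern) -> np.ndarray:
    """Gray levels floor(I_tilde / 32), integers 0..7 (255 maps to 7)."""
    return stretched.values // 32


def glcm(stretched: StretchedPattern, direction: str, rng: AngularRange) -> GLCM:
    """Ordered co-occurrence counts with offset exactly +1 along theta or phi.

    Both pixels of a pair must lie inside the (inclusive) range; there is no
    wrap-around in theta and no cyclic wrap in phi — the duplicated phi=360
    column is dropped before pairing.
    """
    if direction not in ("theta", "phi"):
        raise ValueError("direction must be 'theta' or 'phi'")
    q = _dedup(quantize(stretched))
    rs, cs = _range_slices(rng)
    block = q[rs, cs]
    if direction == "theta":
        a, b = block[:-1, :], block[1:, :]
    else:
        a, b = block[:, :-1], block[:, 1:]
    if a.size == 0:
        raise ValueError(
            f"range {rng.name!r} too thin to form any pair along {direction}"
        )
    counts = np.zeros((N_GRAY, N_GRAY), dtype=np.int64)
    np.add.at(counts, (a.ravel(), b.ravel()), 1)
    return GLCM(counts=counts, direction=direction, range=rng)


def normalize_glcm(g: GLCM) -> np.ndarray:
    """Counts normalized to a probability matrix p(i, j) summing to 1."""
    total = g.counts.sum()
    if total == 0:
        raise ValueError("empty GLCM cannot be normalized")
    return g.counts / total


def haralick_contrast(p: np.ndarray) -> float:
    """Haralick contrast sum_ij |i - j|^2 p(i, j); lies in [0, 49] for 8 levels."""
    i, j = np.indices(p.shape)
    return float(np.sum((i - j) ** 2 * p))


def feature_set(pattern: ScatteringPattern, ranges=DEFAULT_RANGES, Io: float = 1.0,
                replicate_id: int = 0, stretch_scope: str = "per_range") -> FeatureSet:
    """Assemble mean intensity, polar/azimuthal contrast and contrast ratio per range.

    ``stretch_scope`` selects whether the 0..255 stretch is recomputed inside
    each angular range (``"per_range"``, default) or computed once over the
    full pattern (``"global"``).  Per-range is the default because a pattern
    spans many decades between the forward peak and the side/high-angle
    bands: under a global stretch those bands occupy only a few gray levels,
    and their share of the gray range shrinks as fluctuation scattering
    raises large-angle intensities — largely cancelling the texture response
    the contrast features are meant to capture.  Stretching within the
    analyzed range keeps the quantization matched to the local dynamic
    range.

    Raises
    ------
    DegeneratePatternError
        If the polar contrast of a range is zero, which leaves the contrast
        ratio undefined (signalled explicitly rather than emitting infinity).
    """
    if stretch_scope not in ("global", "per_range"):
        raise ValueError("stretch_scope must be 'global' or 'per_range'")
    stretched_global = contrast_stretch(pattern) if stretch_scope == "global" else None
    per_range = {}
    for rng in ranges:
        if stretch_scope == "global":
            stretched = stretched_global
        else:
            rs, cs = _range_slices(rng)
            sub = np.zeros_like(pattern.intensity)
            sub[rs, cs] = pattern.intensity[rs, cs]
            # restrict stretch to range pixels by stretching the sub-block only
            block = pattern.intensity[rs, cs]
            L = _log_intensity(block)
            lo, hi = float(L.min()), float(L.max())
            full = np.zeros((181, 361), dtype=np.int64)
            if hi > lo:
                full[rs, cs] = np.rint(255.0 * (L - lo) / (hi - lo)).astype(np.int64)
            stretched = StretchedPattern(values=full, source_min=lo, source_max=hi,
                                         degenerate=hi == lo)
        c_theta = haralick_contrast(normalize_glcm(glcm(stretched, "theta", rng)))
        c_phi = haralick_contrast(normalize_glcm(glcm(stretched, "phi", rng)))
        if c_theta == 0.0:
            raise DegeneratePatternError(
                f"polar contrast is zero over range {rng.name!r}; contrast ratio undefined"
            )
        per_range[rng.name] = {
            "mean_intensity": mean_log_intensity(pattern, rng, Io),
            "contrast_theta": c_theta,
            "contrast_phi": c_phi,
            "contrast_ratio": c_phi / c_theta,
        }
    return FeatureSet(per_range=per_range, replicate_id=replicate_id,
                      provenance=dict(pattern.provenance))


def aggregate_replicates(sets: list[FeatureSet]) -> dict:
    """Mean and standard error (sample std / sqrt(k)) of each feature over replicates.

    Returns ``{range name: {feature name: (mean, se)}}``; with a single
    replicate the standard error is undefined and reported as NaN.
    """
    if not sets:
        raise ValueError("no replicates to aggregate")
    names = list(sets[0].per_range)
    out: dict = {}
    k = len(sets)
    for rng_name in names:
        out[rng_name] = {}
        for feat in FEATURE_NAMES:
            vals = np.array([s.per_range[rng_name][feat] for s in sets])
            se = float(vals.std(ddof=1) / np.sqrt(k)) if k > 1 else float("nan")
            out[rng_name][feat] = (float(vals.mean()), se)
    return out
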