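"""GLCM/contrast features against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucscatter.features import (
    AngularRange,
    DEFAULT_RANGES,
    StretchedPattern,
    DegeneratePatternError,
    mean_log_intensity,
    contrast_stretch,
    quantize,
    glcm,
    normalize_glcm,
    haralick_contrast,
    feature_set,
    aggregate_replicates,
)

SIDE = DEFAULT_RANGES[1]


def brute_force_glcm(levels: np.ndarray, direction: str) -> np.ndarray:
    """Reference pair counting with explicit loops (ordered pairs, offset +1)."""
    counts = np.zeros((8, 8), dtype=np.int64)
    rows, cols = levels.shape
    if direction == "theta":
        for r in range(rows - 1):
            for c in range(cols):
                counts[levels[r, c], levels[r + 1, c]] += 1
    else:
        for r in range(rows):
            for c in range(cols - 1):
                counts[levels[r, c], levels[r, c + 1]] += 1
    return counts


def stretched_from_values(values: np.ndarray) -> StretchedPattern:
    full = np.zeros((181, 361), dtype=np.int64)
    full[: values.shape[0], : values.shape[1]] = values
    return StretchedPattern(values=full, source_min=0.0, source_max=1.0)


class TestMeanLogIntensity:
    def test_reference_scalings(self, pattern_factory):
        pat = pattern_factory(np.full((181, 361), 5.0))
        assert mean_log_intensity(pat, SIDE, Io=5.0) == pytest.approx(0.0, abs=1e-12)
        assert mean_log_intensity(pat, SIDE, Io=0.05) == pytest.approx(2.0, abs=1e-12)

    def test_against_double_loop(self, pattern_factory):
        rng = np.random.default_rng(1)
        I = rng.lognormal(size=(181, 361))
        pat = pattern_factory(I)
        acc, cnt = 0.0, 0
        for th in range(SIDE.theta_min, SIDE.theta_max + 1):
            for ph in range(0, 360):  # deduplicated phi grid
                acc += np.log10(I[th, ph])
                cnt += 1
        assert mean_log_intensity(pat, SIDE, Io=1.0) == pytest.approx(acc / cnt, abs=1e-12)

    def test_nonpositive_io_refused(self, pattern_factory):
        with pytest.raises(ValueError, match="Io"):
            mean_log_intensity(pattern_factory(np.ones((181, 361))), SIDE, Io=0.0)


class TestContrastStretch:
    def test_two_valued_pattern_hits_bounds(self, pattern_factory):
        I = np.full((181, 361), 1.0)
        I[::2] = 10.0
        s = contrast_stretch(pattern_factory(I))
        assert set(np.unique(s.values)) == {0, 255}

    def test_constant_pattern_degenerate(self, pattern_factory):
        s = contrast_stretch(pattern_factory(np.full((181, 361), 3.0)))
        assert s.degenerate and np.all(s.values == 0)

    def test_linear_ramp_uniform_coverage(self, pattern_factory):
        L = np.tile(np.linspace(0.0, 1.0, 361), (181, 1))
        s = contrast_stretch(pattern_factory(10.0**L))
        expected = np.rint(255.0 * L).astype(np.int64)
        np.testing.assert_array_equal(s.values, expected)

    def test_affine_invariance_of_stretch(self, pattern_factory):
        """L -> aL + b (a > 0) leaves the stretched pattern unchanged.

        L is kept within a few decades so the dynamic range stays clear of
        the relative intensity floor, where the invariance genuinely holds.
        """
        rng = np.random.default_rng(2)
        L = rng.uniform(0.0, 1.0, size=(181, 361))
        s1 = contrast_stretch(pattern_factory(10.0**L))
        s2 = contrast_stretch(pattern_factory(10.0 ** (2.5 * L - 1.0)))
        np.testing.assert_array_equal(s1.values, s2.values)


class TestGLCM:
    def test_constant_side_range_pair_counts(self):
        """Pair-count arithmetic on the inclusive side range (101 theta rows, 360 phi cols)."""
        s = StretchedPattern(values=np.zeros((181, 361), dtype=np.int64),
                             source_min=0.0, source_max=1.0)
        g_theta = glcm(s, "theta", SIDE)
        g_phi = glcm(s, "phi", SIDE)
        assert g_theta.counts[0, 0] == 100 * 360
        assert g_theta.counts.sum() == 100 * 360
        assert g_phi.counts[0, 0] == 101 * 359
        assert g_phi.counts.sum() == 101 * 359

    def test_alternating_columns(self):
        vals = np.zeros((181, 361), dtype=np.int64)
        vals[:, 1::2] = 255
        s = StretchedPattern(values=vals, source_min=0.0, source_max=1.0)
        g_phi = glcm(s, "phi", SIDE).counts
        g_theta = glcm(s, "theta", SIDE).counts
        assert g_phi[0, 7] > 0 and g_phi[7, 0] > 0
        assert g_phi.sum() == g_phi[0, 7] + g_phi[7, 0]
        assert g_theta.sum() == g_theta[0, 0] + g_theta[7, 7]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force(self, seed):
        """Vectorized counting equals the double-loop oracle on random arrays/ranges."""
        rng = np.random.default_rng(seed)
        rows = int(rng.integers(2, 30))
        cols = int(rng.integers(2, 30))
        levels = rng.integers(0, 8, size=(rows, cols))
        arange = AngularRange("test", 0, rows - 1, 0, cols - 1)
        s = stretched_from_values(levels * 32)
        for direction in ("theta", "phi"):
            got = glcm(s, direction, arange).counts
            np.testing.assert_array_equal(got, brute_force_glcm(levels, direction))

    def test_255_maps_to_level_7(self):
        vals = np.full((181, 361), 255, dtype=np.int64)
        s = StretchedPattern(values=vals, source_min=0.0, source_max=1.0)
        assert quantize(s).max() == 7
        assert glcm(s, "theta", SIDE).counts[7, 7] == 100 * 360

    def test_thin_range_refused(self):
        s = StretchedPattern(values=np.zeros((181, 361), dtype=np.int64),
                             source_min=0.0, source_max=1.0)
        thin = AngularRange("thin", 10, 11, 0, 0 + 1)
        # one column only -> no phi pair after range restriction
        thin_phi = AngularRange("thin_phi", 10, 20, 5, 5 + 1)
        g = glcm(s, "phi", thin_phi)  # two columns -> fine
        assert g.counts.sum() == 11 * 1


class TestContrast:
    def test_extreme_and_diagonal(self):
        p = np.zeros((8, 8))
        p[0, 7] = p[7, 0] = 0.5
        assert haralick_contrast(p) == 49.0
        d = np.eye(8) / 8.0
        assert haralick_contrast(d) == 0.0

    def test_against_direct_sum(self):
        rng = np.random.default_rng(3)
        p = rng.random((8, 8))
        p /= p.sum()
        direct = sum(abs(i - j) ** 2 * p[i, j] for i in range(8) for j in range(8))
        assert haralick_contrast(p) == pytest.approx(direct, abs=1e-12)

    def test_normalization(self):
        s = StretchedPattern(values=np.zeros((181, 361), dtype=np.int64),
                             source_min=0.0, source_max=1.0)
        g = glcm(s, "theta", SIDE)
        p = normalize_glcm(g)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(p > 0, g.counts > 0)

    def test_uniform_counts_normalize_flat(self):
        from nucscatter.features import GLCM
        g = GLCM(counts=np.full((8, 8), 5, dtype=np.int64), direction="theta", range=SIDE)
        np.testing.assert_allclose(normalize_glcm(g), 1.0 / 64.0)

    def test_level_translation_invariance(self):
        """Shifting all gray levels by a constant leaves contrast unchanged."""
        rng = np.random.default_rng(4)
        levels = rng.integers(0, 5, size=(40, 50))
        a1 = AngularRange("t", 0, 39, 0, 49)
        s1 = stretched_from_values(levels * 32)
        s2 = stretched_from_values((levels + 3) * 32)
        for direction in ("theta", "phi"):
            c1 = haralick_contrast(normalize_glcm(glcm(s1, direction, a1)))
            c2 = haralick_contrast(normalize_glcm(glcm(s2, direction, a1)))
            assert c1 == pytest.approx(c2, abs=1e-12)

    def test_directional_constancy_gives_zero_contrast(self, pattern_factory):
        """Patterns constant along phi (or theta) have zero contrast in that direction."""
        I_phi_const = np.tile(np.logspace(0, 3, 181)[:, None], (1, 361))
        s = contrast_stretch(pattern_factory(I_phi_const))
        assert haralick_contrast(normalize_glcm(glcm(s, "phi", SIDE))) == 0.0
        I_theta_const = np.tile(np.logspace(0, 3, 361)[None, :], (181, 1))
        s2 = contrast_stretch(pattern_factory(I_theta_const))
        assert haralick_contrast(normalize_glcm(glcm(s2, "theta", SIDE))) == 0.0


class TestFeatureSet:
    def test_constant_pattern_signals_undefined_ratio(self, pattern_factory):
        with pytest.raises(DegeneratePatternError):
            feature_set(pattern_factory(np.full((181, 361), 2.0)))

    def test_alternating_columns_error_path(self, pattern_factory):
        I = np.ones((181, 361))
        I[:, 1::2] = 1000.0
        with pytest.raises(DegeneratePatternError):
            feature_set(pattern_factory(I))

    def test_assembles_all_features(self, pattern_factory):
        rng = np.random.default_rng(5)
        pat = pattern_factory(rng.lognormal(sigma=2.0, size=(181, 361)))
        fs = feature_set(pat)
        for rng_name in ("small_angle", "side", "high_angle"):
            feats = fs.per_range[rng_name]
            assert feats["contrast_theta"] > 0 and feats["contrast_phi"] > 0
            assert feats["contrast_ratio"] == pytest.approx(
                feats["contrast_phi"] / feats["contrast_theta"])

    def test_stretch_scope_switch(self, pattern_factory):
        rng = np.random.default_rng(6)
        pat = pattern_factory(rng.lognormal(sigma=2.0, size=(181, 361)))
        fs_local = feature_set(pat, stretch_scope="per_range")
        fs_global = feature_set(pat, stretch_scope="global")
        assert fs_local.per_range.keys() == fs_global.per_range.keys()
        with pytest.raises(ValueError, match="stretch_scope"):
            feature_set(pat, stretch_scope="rows")


class TestAggregation:
    def test_identical_replicates_zero_se(self, pattern_factory):
        rng = np.random.default_rng(7)
        pat = pattern_factory(rng.lognormal(sigma=2.0, size=(181, 361)))
        fs = feature_set(pat)
        agg = aggregate_replicates([fs, fs, fs])
        for feats in agg.values():
            for mean, se in feats.values():
                assert se == 0.0

    def test_three_replicates_match_hand_formula(self, pattern_factory):
        rng = np.random.default_rng(8)
        sets = [feature_set(pattern_factory(rng.lognormal(sigma=2.0, size=(181, 361))),
                            replicate_id=k) for k in range(3)]
        agg = aggregate_replicates(sets)
        vals = np.array([s.per_range["side"]["contrast_phi"] for s in sets])
        mean, se = agg["side"]["contrast_phi"]
        assert mean == pytest.approx(vals.mean(), abs=1e-12)
        assert se == pytest.approx(vals.std(ddof=1) / np.sqrt(3), abs=1e-12)

    def test_single_replicate_se_undefined(self, pattern_factory):
        rng = np.random.default_rng(9)
        fs = feature_set(pattern_factory(rng.lognormal(sigma=2.0, size=(181, 361))))
        agg = aggregate_replicates([fs])
        for feats in agg.values():
            for mean, se in feats.values():
                assert np.isnan(se)
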