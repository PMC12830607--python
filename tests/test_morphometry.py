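"""Unit and property tests for the profile metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimorph import morphometry as mm
from epimorph.io_formats import ConfigurationError

from naive_oracles import (
    naive_exceedance,
    naive_ra,
    naive_rolling_sd,
    naive_rz,
    naive_skewness,
    naive_smooth,
    naive_zscores,
)

profiles = st.lists(
    st.floats(min_value=1.0, max_value=500.0, allow_nan=False),
    min_size=5, max_size=200,
).filter(lambda xs: max(xs) > min(xs))  # nonzero variance


class TestStandardize:
    def test_hand_computed_zscores(self):
        z = mm.standardize([1, 2, 3, 4, 5]).z_values
        np.testing.assert_allclose(
            z, [-1.4142, -0.7071, 0.0, 0.7071, 1.4142], atol=5e-5
        )

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = mm.standardize(rng.normal(70, 9, 400)).z_values
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_constant_profile_maps_to_zero(self):
        z = mm.standardize([80.0] * 10)
        assert z.scale_um == 0
        assert np.all(z.z_values == 0)

    def test_idempotent_on_standardized_data(self):
        z1 = mm.standardize([3.0, 7.0, 5.0, 9.0, 1.0]).z_values
        z2 = mm.standardize(z1).z_values
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_external_scope_center_scale(self):
        z = mm.standardize([75.0, 85.0], center=80.0, scale=5.0)
        np.testing.assert_allclose(z.z_values, [-1.0, 1.0])

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            mm.standardize([])


class TestSmooth:
    def test_window_one_is_identity(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0]
        np.testing.assert_array_equal(mm.smooth(x, 1), x)

    def test_center_of_alternating_profile(self):
        sm = mm.smooth([0.0, 10.0, 0.0, 10.0, 0.0], 5)
        assert sm[2] == pytest.approx(4.0)

    def test_constant_profile_unchanged(self):
        np.testing.assert_allclose(mm.smooth([7.0] * 9, 5), [7.0] * 9)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            mm.smooth([1.0, 2.0, 3.0], 4)

    @given(profiles)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_shrunken_window_oracle(self, xs):
        np.testing.assert_allclose(mm.smooth(xs, 5), naive_smooth(xs, 5),
                                   rtol=1e-9)


class TestRoughness:
    def test_all_zero_profile(self):
        assert mm.roughness(np.zeros(10)) == (0.0, 0.0)

    def test_hand_computed_values(self):
        z = np.array([-1.4142, -0.7071, 0.0, 0.7071, 1.4142])
        ra, rz = mm.roughness(z)
        assert ra == pytest.approx(0.8485, abs=5e-5)
        assert rz == pytest.approx(2.8284, abs=5e-5)

    def test_gaussian_ra_expectation(self):
        # E|Z| = sqrt(2/pi) for standard normal z
        rng = np.random.default_rng(42)
        z = mm.standardize(rng.normal(size=100_000)).z_values
        ra, _ = mm.roughness(z)
        assert ra == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    @given(profiles)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rz_bounds_ra(self, xs):
        ra, rz = mm.roughness(np.asarray(xs))
        assert rz >= ra >= 0


class TestRollingSD:
    def test_constant_profile_all_zero(self):
        vals, summary = mm.rolling_sd([5.0] * 10, 5)
        assert np.all(vals == 0) and summary == 0

    def test_hand_computed_alternating(self):
        vals, summary = mm.rolling_sd([0.0, 1.0, 0.0, 1.0, 0.0], 5)
        assert vals.size == 1
        assert summary == pytest.approx(0.5477225575, abs=1e-9)

    def test_bump_raises_local_variability(self):
        flat = np.full(100, 80.0)
        bumped = flat.copy()
        x = np.arange(100.0)
        bumped += 40.0 * np.exp(-((x - 50) ** 2) / (2 * 3.0**2))
        assert mm.rolling_sd(bumped, 5)[1] > mm.rolling_sd(flat, 5)[1]

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError, match="window"):
            mm.rolling_sd([1.0, 2.0], 5)


class TestSkewness:
    def test_symmetric_profile_zero(self):
        assert mm.skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_one_outlier(self):
        # m2 = 16, m3 = 96 -> g1 = 96 / 64 = 1.5
        assert mm.skewness([0, 0, 0, 0, 10]) == pytest.approx(1.5)

    @given(profiles)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mirror_antisymmetry(self, xs):
        x = np.asarray(xs)
        assert mm.skewness(-x) == pytest.approx(-mm.skewness(x), abs=1e-8)

    def test_zero_variance_reported_missing(self):
        assert np.isnan(mm.skewness([4.0, 4.0, 4.0]))


class TestExceedance:
    def test_all_zero(self):
        assert mm.exceedance(np.zeros(5)) == (0.0, 0.0, 0.0)

    def test_hand_counted(self):
        z = np.array([-1.4142, -0.7071, 0.0, 0.7071, 1.4142])
        assert mm.exceedance(z) == (0.4, 0.0, 0.0)

    def test_gaussian_tail_fractions(self):
        rng = np.random.default_rng(7)
        z = mm.standardize(rng.normal(size=100_000)).z_values
        f1, f2, f3 = mm.exceedance(z)
        assert f1 == pytest.approx(0.3173, abs=0.01)
        assert f2 == pytest.approx(0.0455, abs=0.004)
        assert f3 == pytest.approx(0.0027, abs=0.0015)

    @given(profiles)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, xs):
        f1, f2, f3 = mm.exceedance(naive_zscores(xs))
        assert 1 >= f1 >= f2 >= f3 >= 0


@given(profiles)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_metrics_match_bruteforce_oracles(xs):
    """Every metric agrees with an independent loop implementation."""
    z = naive_zscores(xs)
    np.testing.assert_allclose(mm.standardize(xs).z_values, z, rtol=1e-9,
                               atol=1e-12)
    ra, rz = mm.roughness(np.asarray(z))
    assert ra == pytest.approx(naive_ra(z), rel=1e-9, abs=1e-12)
    assert rz == pytest.approx(naive_rz(z), rel=1e-9, abs=1e-12)
    vals, _ = mm.rolling_sd(xs, 5)
    np.testing.assert_allclose(vals, naive_rolling_sd(xs, 5), rtol=1e-9,
                               atol=1e-12)
    assert mm.skewness(xs) == pytest.approx(naive_skewness(xs), rel=1e-9,
                                            abs=1e-12)
    for frac, k in zip(mm.exceedance(z), (1, 2, 3)):
        assert frac == pytest.approx(naive_exceedance(z, k), abs=1e-12)


@given(profiles, st.floats(min_value=0.1, max_value=10.0),
       st.floats(min_value=-50.0, max_value=50.0))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_standardized_metrics_affine_invariant(xs, a, b):
    """Ra, Rz, skewness and exceedance ignore affine rescaling a*x + b (a>0)."""
    x = np.asarray(xs)
    y = a * x + b
    zx = mm.standardize(x).z_values
    zy = mm.standardize(y).z_values
    np.testing.assert_allclose(mm.roughness(zx), mm.roughness(zy),
                               rtol=1e-7, atol=1e-9)
    assert mm.skewness(x) == pytest.approx(mm.skewness(y), rel=1e-6, abs=1e-8)
    for k, fx, fy in zip((1.0, 2.0, 3.0), mm.exceedance(zx), mm.exceedance(zy)):
        if np.min(np.abs(np.abs(zx) - k)) > 1e-6:  # k not tied to a sample
            assert fx == fy


class TestSummarizeEye:
    @staticmethod
    def _frame(thicknesses):
        import pandas as pd

        n = len(thicknesses)
        return pd.DataFrame(
            {"animal_id": "P1", "eye": "right", "group": "study",
             "region": "unspecified", "slide_id": "A",
             "position_um": np.arange(n) * 10.0,
             "thickness_um": thicknesses}
        )

    def test_constant_eye(self):
        s = mm.summarize_eye(self._frame([80.0] * 100))
        assert s.mean_um == s.min_um == s.max_um == 80.0
        assert s.range_um == 0 and s.ra == 0 and s.rz == 0
        assert (s.frac_exceed_1sd, s.frac_exceed_2sd, s.frac_exceed_3sd) == (0, 0, 0)

    def test_summary_invariants_on_random_profiles(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(5, 300))
            x = rng.gamma(9.0, 9.0, size=n) + 1.0
            s = mm.summarize_eye(self._frame(x))
            assert s.min_um <= s.mean_um <= s.max_um
            assert s.range_um == pytest.approx(s.max_um - s.min_um)
            assert s.rz >= s.ra >= 0
            assert 1 >= s.frac_exceed_1sd >= s.frac_exceed_2sd >= s.frac_exceed_3sd >= 0

    def test_per_animal_scope_pools_both_eyes(self, cohort):
        df, _ = cohort
        per_animal = mm.summarize_cohort(df, mm.MorphometryConfig())
        per_eye = mm.summarize_cohort(
            df, mm.MorphometryConfig(standardize_scope="per_eye"))
        # pooled scope rescales z, so Rz differs between the scopes
        assert not np.allclose(per_animal["rz"], per_eye["rz"])
        assert set(per_animal["group"]) == {"study", "control"}
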