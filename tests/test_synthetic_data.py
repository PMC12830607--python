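"""Determinism, ground-truth bookkeeping and injected structure of the generators."""

import numpy as np
import pandas as pd
import pytest

from epimorph import synthetic_data as sd


class TestGenerateProfile:
    def test_noise_free_control_is_exact_baseline(self):
        spec = sd.SyntheticCohortSpec(baseline_mean_um=80.0, baseline_sd_um=0.0,
                                      n_points_per_eye=100,
                                      hotspot_amplitude_um=0.0, seed=0)
        prof, truth = sd.generate_profile(spec, "control")
        assert np.all(prof.thickness_um == 80.0)
        assert len(prof) == 100
        assert truth.empty

    def test_same_seed_identical_output(self):
        spec = sd.SyntheticCohortSpec(seed=123)
        p1, t1 = sd.generate_profile(spec, "study")
        p2, t2 = sd.generate_profile(spec, "study")
        np.testing.assert_array_equal(p1.thickness_um, p2.thickness_um)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_bump_range_equals_amplitude(self):
        spec = sd.SyntheticCohortSpec(baseline_sd_um=0.0, hotspot_count=1,
                                      hotspot_amplitude_um=40.0,
                                      hotspot_sign="thickening", seed=9)
        prof, truth = sd.generate_profile(spec, "study")
        rng_um = prof.thickness_um.max() - prof.thickness_um.min()
        assert rng_um == pytest.approx(40.0, rel=0.01)
        # peak is sampled exactly: the bump center sits on the grid
        center = truth["center_um"].iloc[0]
        assert center in prof.positions_um

    def test_extreme_thinning_everywhere_rejected(self):
        spec = sd.SyntheticCohortSpec(baseline_mean_um=20.0, baseline_sd_um=0.0,
                                      floor_um=19.0, hotspot_count=0, seed=0)
        prof, _ = sd.generate_profile(spec, "control")  # above floor: fine
        assert np.all(prof.thickness_um == 20.0)
        bad = sd.SyntheticCohortSpec(baseline_mean_um=20.0, baseline_sd_um=0.0,
                                     floor_um=19.0, hotspot_count=1,
                                     hotspot_amplitude_um=500.0,
                                     hotspot_width_um=1e6,
                                     hotspot_sign="thinning", seed=0)
        with pytest.raises(sd.GenerationError):
            sd.generate_profile(bad, "study")

    def test_amplitude_monotone_in_profile_range(self):
        ranges = []
        for amp in (0.0, 10.0, 20.0, 40.0):
            spec = sd.SyntheticCohortSpec(baseline_sd_um=0.0, hotspot_count=2,
                                          hotspot_amplitude_um=amp, seed=77)
            prof, _ = sd.generate_profile(spec, "study")
            ranges.append(prof.thickness_um.max() - prof.thickness_um.min())
        assert all(a <= b + 1e-12 for a, b in zip(ranges, ranges[1:]))


class TestGenerateCohort:
    def test_counts(self, cohort_spec):
        df, truth = sd.generate_cohort(cohort_spec)
        eyes = df.groupby(["animal_id", "eye"]).ngroups
        assert eyes == 2 * cohort_spec.n_animals
        assert len(truth) == cohort_spec.n_animals * cohort_spec.hotspot_count
        # slides restart their positions at zero
        assert (df.groupby(["animal_id", "eye", "slide_id"])["position_um"]
                .min() == 0).all()

    def test_cohort_determinism(self, cohort_spec):
        df1, t1 = sd.generate_cohort(cohort_spec)
        df2, t2 = sd.generate_cohort(cohort_spec)
        pd.testing.assert_frame_equal(df1, df2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_written_artifacts(self, tmp_path, cohort_spec):
        sd.generate_cohort(cohort_spec, out_dir=tmp_path)
        assert (tmp_path / "measurements.csv").exists()
        assert (tmp_path / "ground_truth_hotspots.csv").exists()
        assert (tmp_path / "cohort_spec.json").exists()


class TestGenerateHistologyImage:
    def test_flat_band_exact_column_heights(self):
        spec = sd.SyntheticImageSpec(width_px=200, height_px=200,
                                     um_per_px=1.0, thickness_um=80.0,
                                     stroma_depth_um=100.0)
        img, truth = sd.generate_histology_image(spec)
        cols = (img.labels == 2).sum(axis=0)
        assert np.all(cols == 80)
        np.testing.assert_array_equal(truth["per_column_thickness_um"], 80.0)

    def test_zero_density_zero_nucleus_pixels(self):
        spec = sd.SyntheticImageSpec(nucleus_density_per_mm2=0.0)
        img, truth = sd.generate_histology_image(spec)
        assert (img.labels == 3).sum() == 0
        assert truth["nucleus_count"] == 0

    def test_poisson_count_statistics(self):
        # mean ground-truth count ~ density x area within Monte-Carlo error
        density = 1082.0
        counts, area = [], None
        for seed in range(20):
            spec = sd.SyntheticImageSpec(
                width_px=1500, height_px=1100, um_per_px=1.0,
                thickness_um=60.0, stroma_depth_um=1000.0,
                nucleus_density_per_mm2=density, seed=seed)
            img, truth = sd.generate_histology_image(spec)
            counts.append(truth["nucleus_count"])
            area = truth["compartment_area_mm2"]
        expected = density * area
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_imprinted_thickness_must_fit(self):
        with pytest.raises(sd.GenerationError):
            sd.SyntheticImageSpec(height_px=50, thickness_um=80.0)


class TestGenerateOCT:
    def test_noise_free_peak_value(self):
        spec = sd.SyntheticOCTSpec(baseline_um=800.0, peak_day=8,
                                   peak_multiplier=1.5, noise_sd_um=0.0)
        s = sd.generate_oct_series(spec)
        assert float(s.loc[s["day"] == 8, "thickness_um"].iloc[0]) == pytest.approx(1200.0)
        assert float(s.loc[s["day"] == -1, "thickness_um"].iloc[0]) == pytest.approx(800.0)

    def test_monotone_rise_and_fall(self):
        spec = sd.SyntheticOCTSpec(noise_sd_um=0.0, peak_day=8)
        s = sd.generate_oct_series(spec).sort_values("day")
        vals = s["thickness_um"].to_numpy()
        days = s["day"].to_numpy()
        pre = vals[days <= 8]
        post = vals[days >= 8]
        assert np.all(np.diff(pre) > 0)
        assert np.all(np.diff(post) < 0)

    def test_day28_recovery_arithmetic(self):
        spec = sd.SyntheticOCTSpec(baseline_um=800.0, peak_multiplier=1.5,
                                   recovery_fraction=0.8, noise_sd_um=0.0)
        s = sd.generate_oct_series(spec)
        assert float(s.loc[s["day"] == 28, "thickness_um"].iloc[0]) == pytest.approx(880.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(sd.GenerationError):
            sd.SyntheticOCTSpec(peak_day=4)  # not in the schedule
        with pytest.raises(sd.GenerationError):
            sd.SyntheticOCTSpec(peak_multiplier=0.9)
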