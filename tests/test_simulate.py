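"""Generator tests: determinism, noiseless limits, moment fidelity and
closure with the analysis modules."""

import numpy as np
import pandas as pd
import pytest

from nucleokin import accumulation, frap, morphometrics, simulate, tracking
from nucleokin.simulate import SimulationRecipe


class TestDeterminism:
    def test_frap_cohort_bit_identical(self):
        truth = simulate.FRAP_PRESETS["unconfined"].replace(n_cells=5)
        a, ta = simulate.simulate_frap_cohort(truth, SimulationRecipe(seed=42))
        b, tb = simulate.simulate_frap_cohort(truth, SimulationRecipe(seed=42))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.intensities, cb.intensities)
        pd.testing.assert_frame_equal(ta, tb)

    def test_all_generators_reproducible(self):
        r = SimulationRecipe(seed=7)
        a1, _ = simulate.simulate_accumulation_cohort(0.3, None, 5, r)
        a2, _ = simulate.simulate_accumulation_cohort(0.3, None, 5, SimulationRecipe(seed=7))
        np.testing.assert_array_equal(a1[0].intensity, a2[0].intensity)
        m1 = simulate.simulate_morphometrics(50, -0.5, SimulationRecipe(seed=7))
        m2 = simulate.simulate_morphometrics(50, -0.5, SimulationRecipe(seed=7))
        pd.testing.assert_frame_equal(m1, m2)
        t1, _ = simulate.simulate_tracks(3, 0.1, 5.0, 10, SimulationRecipe(seed=7))
        t2, _ = simulate.simulate_tracks(3, 0.1, 5.0, 10, SimulationRecipe(seed=7))
        np.testing.assert_array_equal(t1[1].x, t2[1].x)
        g1, _ = simulate.simulate_growth_study([simulate.GrowthArmTruth("a")], 2,
                                               SimulationRecipe(seed=7))
        g2, _ = simulate.simulate_growth_study([simulate.GrowthArmTruth("a")], 2,
                                               SimulationRecipe(seed=7))
        np.testing.assert_array_equal(g1[0].volumes, g2[0].volumes)

    def test_different_seeds_differ(self):
        truth = simulate.FRAP_PRESETS["unconfined"].replace(n_cells=3)
        a, _ = simulate.simulate_frap_cohort(truth, SimulationRecipe(seed=1))
        b, _ = simulate.simulate_frap_cohort(truth, SimulationRecipe(seed=2))
        assert not np.array_equal(a[0].intensities, b[0].intensities)


class TestFrapGenerator:
    def test_noiseless_limit_matches_closed_form(self):
        truth = simulate.FRAP_PRESETS["unconfined"].replace(
            between_cell_cv=1e-12, noise_sd=1e-15, n_cells=2)
        curves, table = simulate.simulate_frap_cohort(truth, SimulationRecipe(seed=0))
        c = frap.normalize_recovery(curves[0])
        row = table.iloc[0]
        t = c.postbleach_times
        expected = row.y0 + row.a_fast * (1 - np.exp(-t / row.tau_fast)) \
            + row.a_slow * (1 - np.exp(-t / row.tau_slow))
        np.testing.assert_allclose(c.postbleach_intensities, expected, atol=1e-9)
        assert int(c.is_prebleach.sum()) == 1
        assert c.prebleach_intensity == pytest.approx(1.0, abs=1e-9)

    def test_noise_calibration_formula(self):
        """sigma^2 must equal (1 - R2) * Var of the model on the grid, with the
        variance computed by brute-force evaluation."""
        t = np.arange(0, 20.0001, 0.2)
        params = {"y0": 0.05, "a_fast": 0.66, "tau_fast": 0.2,
                  "a_slow": 0.05, "tau_slow": 5.0}
        sd = simulate.calibrated_noise_sd(params, t, target_r_squared=0.986)
        f = params["y0"] + params["a_fast"] * (1 - np.exp(-t / params["tau_fast"])) \
            + params["a_slow"] * (1 - np.exp(-t / params["tau_slow"]))
        assert sd**2 == pytest.approx((1 - 0.986) * np.var(f), rel=1e-12)

    def test_rejects_invalid_truth(self):
        with pytest.raises(ValueError, match="tau_slow"):
            simulate.FrapGroundTruth("x", 0.05, 0.75, 0.05, tau_fast_mean=5.0,
                                     tau_slow_mean=1.0, between_cell_cv=0.1, n_cells=5)
        with pytest.raises(ValueError, match="noise_sd"):
            simulate.FrapGroundTruth("x", 0.05, 0.75, 0.05, 0.2, 5.0,
                                     between_cell_cv=0.1, n_cells=5, noise_sd=-1.0)


class TestAccumulationGenerator:
    def test_zero_contamination_all_kept(self):
        tracks, truth, preset = simulate.simulate_accumulation_preset(
            "tubacin", 50, SimulationRecipe(seed=3))
        _, summary = accumulation.cohort_rates(tracks)
        assert summary["n_kept"] == 50

    def test_mean_ols_slope_matches_truth_within_3se(self):
        """Monte-Carlo moment oracle: over 500 clean tracks the mean per-track
        OLS slope lies within 3 standard errors of the configured rate."""
        rate = 0.30
        tracks, truth = simulate.simulate_accumulation_cohort(
            rate, None, 500, SimulationRecipe(seed=11))
        slopes = []
        for tr in tracks:
            ft = accumulation.to_fold_change(tr)
            t, y = ft.times, ft.intensity
            slopes.append(np.polyfit(t, y, 1)[0])
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - rate) < 3 * se

    def test_plateau_reaches_final_fold(self):
        tracks, truth = simulate.simulate_accumulation_cohort(
            0.269, 1.76, 200, SimulationRecipe(seed=5))
        finals = [accumulation.to_fold_change(tr).intensity[-1] for tr in tracks]
        assert np.mean(finals) == pytest.approx(1.76, abs=0.05)

    def test_contamination_fraction_validated(self):
        with pytest.raises(ValueError, match="contamination"):
            simulate.simulate_accumulation_cohort(
                0.3, None, 5, SimulationRecipe(seed=0, contamination_fraction=1.5))

    def test_contaminated_tracks_labelled(self):
        tracks, truth = simulate.simulate_accumulation_cohort(
            0.3, None, 40, SimulationRecipe(seed=9, contamination_fraction=0.25))
        assert truth["contaminated"].sum() == 10


class TestMorphometricsGenerator:
    def test_perfect_anticorrelation_is_exact(self):
        table = simulate.simulate_morphometrics(100, -1.0, SimulationRecipe(seed=2))
        r, _, _, _ = morphometrics.circularity_intensity_correlation(table)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_rho_out_of_range(self):
        with pytest.raises(ValueError, match="correlation_rho"):
            simulate.simulate_morphometrics(10, -1.5, SimulationRecipe(seed=0))

    def test_sample_correlation_approaches_rho(self):
        table = simulate.simulate_morphometrics(5000, -0.474, SimulationRecipe(seed=4))
        r, _, _, _ = morphometrics.circularity_intensity_correlation(table)
        assert r == pytest.approx(-0.474, abs=0.05)

    def test_rendered_disks_measure_round(self):
        """Rasterization oracle: rendering axis-ratio-1 nuclei must yield
        measured circularity >= 0.9 for every object."""
        table, labels, channels = simulate.simulate_morphometrics(
            10, 0.0, SimulationRecipe(seed=6), render_images=True,
            circularity_sd=1e-9, circularity_mean=2.0)  # clipped to 1 => disks
        measured = morphometrics.measure_objects(labels, channels)
        assert len(measured) == 10
        assert (measured["circularity"] >= 0.9).all()

    def test_render_round_trips_intensity(self):
        table, labels, channels = simulate.simulate_morphometrics(
            16, -0.474, SimulationRecipe(seed=8), render_images=True)
        measured = morphometrics.measure_objects(labels, channels)
        measured = morphometrics.normalize_to_reference(measured, "protein", "reference")
        merged = table.merge(measured, on="object_id")
        # 16-bit quantization at reference level 1000 bounds the ratio error
        np.testing.assert_allclose(merged["normalized_intensity_x"],
                                   merged["normalized_intensity_y"], atol=2e-3)


class TestTrackGenerator:
    def test_zero_velocity_is_exactly_zero(self):
        tracks, _ = simulate.simulate_tracks(5, 0.0, 5.0, 20, SimulationRecipe(seed=1))
        for tr in tracks:
            res = tracking.mean_velocity(tr, 5.0)
            assert res.mean_velocity == 0.0

    def test_velocity_recovered(self):
        tracks, _ = simulate.simulate_tracks(200, 0.0838, 5.0, 100, SimulationRecipe(seed=2))
        _, summary = tracking.cohort_velocity(tracks, 5.0)
        assert summary["mean_velocity"]["mean"] == pytest.approx(0.0838, rel=0.05)

    def test_doubling_frame_interval_halves_velocity(self):
        """At a fixed step-length distribution the computed velocity scales
        as 1 / frame_interval."""
        tracks, _ = simulate.simulate_tracks(3, 0.1, 5.0, 50, SimulationRecipe(seed=3))
        for tr in tracks:
            v1 = tracking.mean_velocity(tr, 5.0).mean_velocity
            stretched = tr.replace(times=tr.times * 2)
            v2 = tracking.mean_velocity(stretched, 10.0).mean_velocity
            assert v2 == pytest.approx(v1 / 2, rel=1e-12)

    def test_nonpositive_frame_interval(self):
        with pytest.raises(ValueError, match="frame_interval"):
            simulate.simulate_tracks(2, 0.1, -5.0, 10, SimulationRecipe(seed=0))


class TestGrowthGenerator:
    def test_zero_noise_single_exponential_is_loglinear(self):
        arm = simulate.GrowthArmTruth("v", v0=100.0, rate_early=0.1, sigma=1e-12)
        curves, _ = simulate.simulate_growth_study([arm], 2, SimulationRecipe(seed=1))
        lv = np.log(curves[0].volumes)
        slope = np.polyfit(curves[0].days, lv, 1)
        assert slope[0] == pytest.approx(0.1, abs=1e-9)
        resid = lv - np.polyval(slope, curves[0].days)
        assert np.abs(resid).max() < 1e-9

    def test_empty_arms_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate.simulate_growth_study([], 3, SimulationRecipe(seed=0))

    def test_twice_weekly_sampling_from_100mm3(self):
        arm = simulate.GrowthArmTruth("v", sigma=1e-12)
        curves, _ = simulate.simulate_growth_study([arm], 1, SimulationRecipe(seed=1))
        np.testing.assert_allclose(np.diff(curves[0].days), 3.5)
        assert curves[0].volumes[0] == pytest.approx(100.0, rel=1e-6)
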