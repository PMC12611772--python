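"""Unit and property tests for the FRAP recovery pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleokin import frap
from nucleokin.datatypes import DegenerateInputError, FrapCurve
from conftest import make_frap_curve


def _raw_curve(intensities, dt=1.0):
    intensities = np.asarray(intensities, dtype=float)
    times = np.arange(intensities.size, dtype=float) * dt
    is_pre = np.zeros(intensities.size, dtype=bool)
    is_pre[0] = True
    return FrapCurve("raw", times, intensities, is_pre)


class TestNormalize:
    def test_constant_series_becomes_unity(self):
        c = frap.normalize_recovery(_raw_curve([100.0] * 15))
        assert np.allclose(c.intensities, 1.0)
        assert c.normalized

    def test_prebleach_division_and_time_origin(self):
        c = frap.normalize_recovery(_raw_curve([200.0, 50.0, 80.0, 120.0]))
        assert c.prebleach_intensity == 1.0
        assert c.postbleach_intensities[0] == pytest.approx(0.25)
        assert c.postbleach_times[0] == 0.0

    @settings(deadline=None, max_examples=25)
    @given(k=st.floats(min_value=1e-3, max_value=1e6, allow_nan=False))
    def test_scale_invariance(self, k):
        base = [200.0, 50.0, 80.0, 120.0, 150.0]
        a = frap.normalize_recovery(_raw_curve(base))
        b = frap.normalize_recovery(_raw_curve([k * v for v in base]))
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-12)

    def test_rejects_nonpositive_prebleach(self):
        with pytest.raises(ValueError, match="pre-bleach"):
            frap.normalize_recovery(_raw_curve([0.0, 10.0, 20.0]))

    def test_rejects_double_normalization(self):
        c = frap.normalize_recovery(_raw_curve([100.0, 25.0, 50.0]))
        with pytest.raises(ValueError, match="already normalized"):
            frap.normalize_recovery(c)


class TestBleachDepthQc:
    @pytest.mark.parametrize("first_post,accepted", [
        (0.20, True),
        (0.25, True),   # boundary is inclusive
        (0.30, False),
    ])
    def test_threshold(self, first_post, accepted):
        c = frap.normalize_recovery(_raw_curve([1.0, first_post, 0.5, 0.7]))
        decision = frap.qc_bleach_depth(c)
        assert decision.accepted is accepted
        if not accepted:
            assert decision.reason == "insufficient_bleach_depth"

    def test_requires_normalized_curve(self):
        with pytest.raises(ValueError, match="normalized"):
            frap.qc_bleach_depth(_raw_curve([100.0, 20.0, 50.0]))


class TestTwoComponentFit:
    def test_noiseless_identifiability(self):
        truth = dict(y0=0.05, a_fast=0.68, tau_fast=0.8, a_slow=0.03, tau_slow=8.0)
        fit = frap.fit_two_component(make_frap_curve(**truth))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        for key, val in truth.items():
            assert getattr(fit, key) == pytest.approx(val, abs=1e-4)

    def test_relabeling_invariance(self):
        """Swapping (A1, tau1) with (A2, tau2) in the generating model leaves
        the (fast, slow) labelling of the fit unchanged."""
        a = make_frap_curve(a_fast=0.6, tau_fast=0.5, a_slow=0.1, tau_slow=6.0)
        b = make_frap_curve(a_fast=0.1, tau_fast=6.0, a_slow=0.6, tau_slow=0.5)
        fa, fb = frap.fit_two_component(a), frap.fit_two_component(b)
        for attr in ("a_fast", "tau_fast", "a_slow", "tau_slow", "y0"):
            assert getattr(fa, attr) == pytest.approx(getattr(fb, attr), abs=1e-6)
        assert fa.tau_fast <= fa.tau_slow

    def test_constant_trace_is_degenerate(self):
        t = np.arange(-0.2, 20.0, 0.2)
        is_pre = np.zeros(t.size, bool)
        is_pre[0] = True
        c = FrapCurve("flat", t, np.full(t.size, 0.2), is_pre, normalized=True)
        with pytest.raises(DegenerateInputError):
            frap.fit_two_component(c)

    def test_too_few_postbleach_points(self):
        c = make_frap_curve(dt=4.0, duration=20.0)  # 6 post-bleach samples
        with pytest.raises(ValueError, match="post-bleach"):
            frap.fit_two_component(c)

    def test_fitter_beats_tau_grid_oracle(self, rng):
        """The fitter's SSE must not exceed a (tau1, tau2) grid search with
        amplitudes solved by linear least squares at each grid point."""
        grid = np.geomspace(0.05, 40.0, 40)
        for _ in range(5):
            c = make_frap_curve(noise_sd=0.01, rng=rng)
            fit = frap.fit_two_component(c)
            t, f = c.postbleach_times, c.postbleach_intensities
            best = np.inf
            for i, t1 in enumerate(grid):
                for t2 in grid[i + 1:]:
                    X = np.column_stack([np.ones_like(t), 1 - np.exp(-t / t1),
                                         1 - np.exp(-t / t2)])
                    coef, _, _, _ = np.linalg.lstsq(X, f, rcond=None)
                    best = min(best, float(((f - X @ coef) ** 2).sum()))
            assert fit.sse <= best + 1e-12

    def test_slow_fraction_error_grows_with_noise(self, rng):
        """Median absolute slow-fraction error is monotone in the noise SD."""
        meds = []
        for sd in (0.005, 0.02, 0.05):
            errs = []
            for _ in range(30):
                c = make_frap_curve(a_fast=0.65, a_slow=0.06, tau_fast=0.3,
                                    tau_slow=5.0, noise_sd=sd, rng=rng)
                fr = frap.fit_two_component(c).pool_fractions()
                errs.append(abs(fr.slow_fraction - 0.06 / 0.71))
            meds.append(np.median(errs))
        assert meds[0] <= meds[1] <= meds[2]


class TestPoolFractions:
    def test_full_mobility(self):
        fit = frap.FrapFitResults("x", y0=0.2, a_fast=0.7, tau_fast=0.5, a_slow=0.1,
                                  tau_slow=5.0, sse=0, sst=1, r_squared=1,
                                  converged=True, n_postbleach=100)
        fr = fit.pool_fractions()
        assert fr.mobile_fraction == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        fit = frap.FrapFitResults("x", y0=0.2, a_fast=0.5, tau_fast=0.5, a_slow=0.1,
                                  tau_slow=5.0, sse=0, sst=1, r_squared=1,
                                  converged=True, n_postbleach=100)
        fr = fit.pool_fractions()
        assert fr.mobile_fraction == pytest.approx(0.75)
        assert fr.slow_fraction == pytest.approx(1.0 / 6.0)
        assert fr.fast_fraction + fr.slow_fraction == pytest.approx(1.0, abs=1e-15)

    def test_degenerate_inputs(self):
        bad = frap.FrapFitResults("x", y0=1.0, a_fast=0.5, tau_fast=0.5, a_slow=0.1,
                                  tau_slow=5.0, sse=0, sst=1, r_squared=1,
                                  converged=True, n_postbleach=100)
        with pytest.raises(ValueError, match="y0"):
            bad.pool_fractions()
        zero = frap.FrapFitResults("x", y0=0.1, a_fast=0.0, tau_fast=0.5, a_slow=0.0,
                                   tau_slow=5.0, sse=0, sst=1, r_squared=1,
                                   converged=True, n_postbleach=100)
        with pytest.raises(ValueError, match="amplitude"):
            zero.pool_fractions()


class TestCompareFractions:
    def test_identical_samples(self):
        res = frap.compare_fractions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        res = frap.compare_fractions(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 10000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += abs(perm[:10].mean() - perm[10:].mean()) >= obs - 1e-12
        p_perm = count / n_perm
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) < 4 * mc_se + 0.005


class TestAnalyzeCohort:
    def test_pipeline_counts_and_columns(self):
        from nucleokin import simulate
        truth = simulate.FRAP_PRESETS["unconfined"].replace(n_cells=8)
        curves, _ = simulate.simulate_frap_cohort(truth, simulate.SimulationRecipe(seed=3))
        table, summary = frap.analyze_cohort(curves)
        assert summary["n_input"] == 8
        assert summary["n_resolved"] <= summary["n_converged"] <= summary["n_qc_pass"]
        assert {"mobile_fraction", "slow_fraction", "r_squared"} <= set(table.columns)
        kept = table[table["resolved"]]
        np.testing.assert_allclose(
            kept["slow_fraction"] + kept["fast_fraction"], 1.0, atol=1e-12)

    def test_shallow_bleach_rejected(self):
        shallow = make_frap_curve(y0=0.4)
        table, summary = frap.analyze_cohort([shallow, make_frap_curve()])
        assert summary["n_qc_pass"] == 1
        assert table.loc[~table["qc_pass"], "qc_reason"].iloc[0] == "insufficient_bleach_depth"
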