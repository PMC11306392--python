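"""Detrending, censored-frame simulation, filtering, regression, scaling,
variance standardisation, smoothing, and the orchestrated workflow."""

import numpy as np
import pytest
from scipy.signal import periodogram

from boldqc.core import (
    ConfoundMatrix,
    Grid,
    TemporalMask,
    Timeseries4D,
    VolumeMap,
)
from boldqc.correction import (
    WorkflowOptions,
    detrend,
    frequency_filter,
    regress_confounds,
    run_workflow,
    scale_intensity,
    simulate_censored,
    smooth_spatial,
    standardize_variance,
)
from boldqc.optimize import baseline_options
from boldqc.phantom import PhantomConfig, make_phantom


class TestDetrend:
    def test_constant_voxel_zero_residual_and_intercept(self, full_mask):
        n = full_mask.count()
        ts = Timeseries4D(np.full((n, 20), 5.0), full_mask, tr=1.0)
        resid, intercepts = detrend(ts)
        assert np.allclose(resid.values, 0, atol=1e-10)
        assert np.allclose(intercepts, 5.0)

    def test_pure_line_removed(self, full_mask):
        n = full_mask.count()
        t = np.arange(30, dtype=float)
        ts = Timeseries4D(np.outer(np.ones(n), 2.0 + 0.3 * t), full_mask, tr=1.0)
        resid, _ = detrend(ts)
        assert np.max(np.abs(resid.values)) < 1e-8 * 10

    def test_intercept_is_retained_frame_mean(self, random_ts, rng):
        keep = rng.random(random_ts.n_frames) > 0.3
        mask = TemporalMask(keep)
        _, intercepts = detrend(random_ts, mask)
        assert np.allclose(intercepts, random_ts.values[:, keep].mean(axis=1))

    def test_order1_matches_normal_equations_on_quadratic(self, full_mask):
        n = full_mask.count()
        t = np.arange(40, dtype=float)
        sig = 1.0 + 0.2 * t + 0.05 * t**2
        ts = Timeseries4D(np.tile(sig, (n, 1)), full_mask, tr=1.0)
        resid, _ = detrend(ts, order=1)
        tc = t - t.mean()
        X = np.column_stack([np.ones_like(tc), tc])
        beta = np.linalg.solve(X.T @ X, X.T @ sig)
        assert np.allclose(resid.values[0], sig - X @ beta, atol=1e-8)

    def test_order2_removes_quadratic(self, full_mask):
        n = full_mask.count()
        t = np.arange(40, dtype=float)
        sig = 1.0 + 0.2 * t + 0.05 * t**2
        ts = Timeseries4D(np.tile(sig, (n, 1)), full_mask, tr=1.0)
        resid, _ = detrend(ts, order=2)
        assert np.max(np.abs(resid.values)) < 1e-8 * np.abs(sig).max()


class TestSimulateCensored:
    def test_no_censoring_is_identity(self, random_ts):
        out = simulate_censored(random_ts, TemporalMask.all_kept(random_ts.n_frames))
        assert np.array_equal(out.values, random_ts.values)

    def test_retained_frames_keep_observed_values(self, random_ts, rng):
        keep = np.ones(random_ts.n_frames, dtype=bool)
        keep[rng.choice(random_ts.n_frames, 10, replace=False)] = False
        out = simulate_censored(random_ts, TemporalMask(keep))
        assert np.allclose(out.values[:, keep], random_ts.values[:, keep])

    def test_sinusoid_peak_frequency_preserved(self, full_mask):
        tr, n = 1.2, 200
        t = np.arange(n) * tr
        rng = np.random.default_rng(7)
        sig = np.sin(2 * np.pi * 0.03 * t)
        ts = Timeseries4D(np.tile(sig, (full_mask.count(), 1)), full_mask, tr=tr)
        keep = np.ones(n, dtype=bool)
        keep[rng.choice(n, 40, replace=False)] = False
        out = simulate_censored(ts, TemporalMask(keep))
        f, p = periodogram(out.values[0], fs=1.0 / tr)
        assert abs(f[np.argmax(p)] - 0.03) <= f[1] - f[0]

    def test_white_noise_variance_bounded(self, full_mask):
        n = 120
        within = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ts = Timeseries4D(rng.standard_normal((full_mask.count(), n)), full_mask, tr=1.0)
            keep = np.ones(n, dtype=bool)
            keep[rng.choice(n, n // 5, replace=False)] = False
            out = simulate_censored(ts, TemporalMask(keep))
            if out.values[:, ~keep].var() <= 2.0 * out.values[:, keep].var():
                within += 1
        assert within == n_seeds

    def test_deterministic(self, random_ts):
        keep = np.ones(random_ts.n_frames, dtype=bool)
        keep[5:12] = False
        a = simulate_censored(random_ts, TemporalMask(keep))
        b = simulate_censored(random_ts, TemporalMask(keep))
        assert np.array_equal(a.values, b.values)


class TestFrequencyFilter:
    def test_edge_trim_frame_count(self, full_mask):
        n = full_mask.count()
        ts = Timeseries4D(np.random.default_rng(0).standard_normal((n, 120)), full_mask, tr=1.2)
        _, edge = frequency_filter(ts, highpass=0.01, edge_trim_s=30.0)
        assert (~edge.keep[:60]).sum() == 25
        assert (~edge.keep[60:]).sum() == 25

    def test_highpass_removes_dc_preserves_passband(self, full_mask):
        tr, n = 1.2, 200
        t = np.arange(n) * tr
        sig = 5.0 + np.sin(2 * np.pi * 0.05 * t)
        ts = Timeseries4D(np.tile(sig, (full_mask.count(), 1)), full_mask, tr=tr)
        out, edge = frequency_filter(ts, highpass=0.01)
        core = out.values[0][edge.keep]
        assert abs(core.mean()) < 0.01  # DC gone: < 1% of unit amplitude
        amp = (core.max() - core.min()) / 2
        assert abs(amp - 1.0) < 0.05  # 0.05 Hz sinusoid within 5%

    def test_no_cutoffs_is_identity(self, random_ts):
        out, edge = frequency_filter(random_ts, None, None)
        assert np.array_equal(out.values, random_ts.values)
        assert edge.keep.all()

    def test_cutoff_above_nyquist_rejected(self, random_ts):
        with pytest.raises(ValueError, match="Nyquist"):
            frequency_filter(random_ts, highpass=1.0)


class TestRegressConfounds:
    def test_own_timecourse_gives_zero_residual(self, full_mask):
        rng = np.random.default_rng(1)
        n = full_mask.count()
        vals = rng.standard_normal((n, 50))
        ts = Timeseries4D(vals, full_mask, tr=1.0)
        X = ConfoundMatrix(vals[3][:, None])
        resid, _, _ = regress_confounds(ts, X)
        assert np.allclose(resid.values[3], 0, atol=1e-10)

    def test_orthogonal_regressor_leaves_data(self, full_mask):
        n = full_mask.count()
        t = np.arange(64, dtype=float)
        y = np.sin(2 * np.pi * 4 * t / 64)
        x = np.cos(2 * np.pi * 4 * t / 64)  # orthogonal over full cycles
        ts = Timeseries4D(np.tile(y, (n, 1)), full_mask, tr=1.0)
        resid, _, _ = regress_confounds(ts, ConfoundMatrix(x[:, None]))
        assert np.allclose(resid.values, ts.values, atol=1e-10)

    def test_beta_matches_pseudoinverse(self, full_mask, rng):
        n = full_mask.count()
        Y = rng.standard_normal((n, 40))
        X = rng.standard_normal((40, 4))
        ts = Timeseries4D(Y, full_mask, tr=1.0)
        _, y_cr, beta = regress_confounds(ts, ConfoundMatrix(X))
        beta_expected = np.linalg.pinv(X) @ Y.T
        assert np.allclose(beta, beta_expected, atol=1e-8)
        assert np.allclose(y_cr.values, (X @ beta_expected).T, atol=1e-8)

    def test_residuals_orthogonal_to_all_columns(self, full_mask, rng):
        Y = rng.standard_normal((full_mask.count(), 60))
        X = rng.standard_normal((60, 5))
        resid, _, _ = regress_confounds(Timeseries4D(Y, full_mask, tr=1.0), ConfoundMatrix(X))
        dots = resid.values @ X
        assert np.max(np.abs(dots)) < 1e-8

    def test_rank_deficient_names_collinear_columns(self, full_mask, rng):
        X = rng.standard_normal((30, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        cm = ConfoundMatrix(X)
        cm.columns.columns = ["a", "b", "dup"]
        ts = Timeseries4D(rng.standard_normal((full_mask.count(), 30)), full_mask, tr=1.0)
        with pytest.raises(ValueError, match="dup"):
            regress_confounds(ts, cm)


class TestScaling:
    def test_grand_mean_percent_bold(self, random_ts):
        intercepts = np.full(random_ts.n_voxels, 50.0)
        out = scale_intensity(random_ts, intercepts, "grand_mean")
        assert np.allclose(out.values, random_ts.values * 2.0)

    def test_voxelwise_z_unit_sd(self, random_ts):
        out = scale_intensity(random_ts, None, "voxelwise_z")
        assert np.allclose(out.values.std(axis=1), 1.0)

    def test_global_sd_unit_total(self, random_ts):
        out = scale_intensity(random_ts, None, "global_sd")
        assert out.values.std() == pytest.approx(1.0)

    def test_grand_mean_requires_intercepts(self, random_ts):
        with pytest.raises(ValueError, match="intercepts"):
            scale_intensity(random_ts, None, "grand_mean")


class TestStandardizeVariance:
    def test_two_voxel_closed_form(self, grid):
        mask_vals = np.zeros(grid.shape, dtype=int)
        mask_vals.reshape(-1)[:2] = 1
        mask = VolumeMap(mask_vals, grid, kind="brain_mask")
        t = np.arange(64.0)
        v1 = np.sin(2 * np.pi * t / 16)
        v2 = 3.0 * np.cos(2 * np.pi * t / 16)
        ts = Timeseries4D(np.vstack([v1, v2]), mask, tr=1.0)
        out = standardize_variance(ts)
        sds = out.values.std(axis=1)
        assert sds[0] == pytest.approx(sds[1])
        assert out.values.std() == pytest.approx(ts.values.std(), abs=1e-8)

    def test_total_sd_conserved_random(self, rng, full_mask):
        for _ in range(20):
            ts = Timeseries4D(
                rng.standard_normal((full_mask.count(), 30)) * rng.uniform(0.5, 3),
                full_mask, tr=1.0,
            )
            out = standardize_variance(ts)
            assert out.values.std() == pytest.approx(ts.values.std(), rel=1e-10)
            assert np.allclose(out.values.std(axis=1), out.values.std(axis=1)[0])

    def test_equal_variance_input_is_fixed_point(self, full_mask, rng):
        phases = rng.uniform(0, 2 * np.pi, full_mask.count())
        t = np.arange(50.0)
        vals = np.sin(2 * np.pi * t / 10 + phases[:, None])
        ts = Timeseries4D(vals, full_mask, tr=1.0)
        out = standardize_variance(ts)
        assert np.allclose(out.values, ts.values, rtol=1e-6)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, random_ts):
        assert smooth_spatial(random_ts, 0.0) is random_ts

    def test_impulse_mass_conserved(self, grid):
        mask = VolumeMap(np.ones(grid.shape, dtype=int), grid, kind="brain_mask")
        vals = np.zeros((mask.count(), 3))
        vals[mask.count() // 2, :] = 1.0
        ts = Timeseries4D(vals, mask, tr=1.0)
        out = smooth_spatial(ts, 0.3)
        assert out.values[:, 0].sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_image_unchanged(self, full_mask):
        ts = Timeseries4D(np.full((full_mask.count(), 3), 4.0), full_mask, tr=1.0)
        out = smooth_spatial(ts, 0.5)
        assert np.allclose(out.values, 4.0, atol=1e-8)


class TestWorkflow:
    def test_defaults_detrend_and_grand_mean_only(self):
        ph = make_phantom(PhantomConfig(n_motion_spikes=0), seed=0)
        res = run_workflow(ph.ts, ph.motion, WorkflowOptions())
        resid, intercepts = detrend(ph.ts)
        expected = scale_intensity(resid, intercepts, "grand_mean")
        assert np.allclose(res.cleaned.values, expected.values)
        assert res.temporal_mask.keep.all()
        assert res.confounds is None

    def test_heavy_censoring_flags_exclusion(self):
        ph = make_phantom(PhantomConfig(n_motion_spikes=20), seed=1)
        res = run_workflow(
            ph.ts, ph.motion, WorkflowOptions(fd_censor_threshold=0.05)
        )
        # 20 spikes x up to 4 frames censored: retained < 2/3 of 200
        assert res.retained_fraction < 2 / 3
        assert res.excluded

    def test_tdof_accounting(self):
        ph = make_phantom(seed=2)
        opt = baseline_options(highpass=0.01)
        res = run_workflow(ph.ts, ph.motion, opt, wm_mask=ph.wm_mask, csf_mask=ph.csf_mask)
        assert res.tdof == res.temporal_mask.n_kept - 6 - 1 - 1

    def test_residuals_orthogonal_to_processed_regressors(self):
        ph = make_phantom(seed=3)
        res = run_workflow(ph.ts, ph.motion, baseline_options())
        X = res.confounds.to_array()
        v = res.cleaned.values - res.cleaned.values.mean(axis=1, keepdims=True)
        Xc = X - X.mean(axis=0)
        denom = np.linalg.norm(v, axis=1)[:, None] * np.linalg.norm(Xc, axis=0)[None, :]
        corr = (v @ Xc) / denom
        assert np.max(np.abs(corr)) < 1e-6

    def test_recensoring_preserves_retained_count_except_edges(self):
        ph = make_phantom(seed=4)
        opt = baseline_options(highpass=0.01)
        res = run_workflow(ph.ts, ph.motion, opt)
        trim = int(np.floor(30.0 / ph.ts.tr))
        inner = res.censor_mask.keep.copy()
        inner[:trim] = False
        inner[-trim:] = False
        assert np.array_equal(res.temporal_mask.keep, inner)

    def test_end_to_end_network_recovery(self):
        """Drift + motion spikes + planted networks: after the full pipeline
        the planted network timecourse is recovered by dual regression."""
        from boldqc.connectivity import dual_regression

        for seed in range(3):
            ph = make_phantom(PhantomConfig(structured_noise_amplitude=0.0), seed=seed)
            opt = baseline_options(highpass=0.01, smoothing_fwhm=0.3)
            res = run_workflow(ph.ts, ph.motion, opt, wm_mask=ph.wm_mask, csf_mask=ph.csf_mask)
            assert np.array_equal(
                np.flatnonzero(bq_fd(ph) > 0.05), ph.truth.spike_frames
            )
            tcs, _ = dual_regression(res.cleaned, ph.priors())
            truth = ph.truth.network_timecourses[0][res.temporal_mask.keep]
            r = abs(np.corrcoef(tcs[0], truth)[0, 1])
            assert r > 0.9

    def test_workflow_deterministic(self):
        ph = make_phantom(seed=5)
        opt = baseline_options(highpass=0.01, seed=11)
        a = run_workflow(ph.ts, ph.motion, opt)
        b = run_workflow(ph.ts, ph.motion, opt)
        assert np.array_equal(a.cleaned.values, b.cleaned.values)


def bq_fd(ph):
    from boldqc.regressors import framewise_displacement

    return framewise_displacement(ph.motion)
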