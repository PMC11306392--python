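"""Scan- and group-level QC metrics against brute-force oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from boldqc.core import ScanQCRecord, Timeseries4D, VolumeMap, map_from_voxels
from boldqc.phantom import make_fd_effect_group
from boldqc.qc import (
    apply_scan_inclusion,
    bold_variability_map,
    category_mean_timecourse,
    confound_correlation,
    cr_sd_map,
    dice,
    distribution_report,
    group_report,
    gs_covariance_map,
    modified_z_outliers,
    network_amplitude,
    network_specificity,
    threshold_top,
)


def record(scan_id="s", dice_=0.6, corr=0.1, amp=10.0, fd=0.01, tdof=150, ret=1.0,
           cr_map=None, mean_cr=1.0):
    return ScanQCRecord(
        scan_id=scan_id, dice_specificity=dice_, confound_correlation=corr,
        amplitude_l2=amp, mean_fd=fd, tdof=tdof, retained_fraction=ret,
        cr_sd_map=cr_map, mean_cr_sd=mean_cr,
    )


class TestDiagnosticMaps:
    def test_variability_constant_voxel_zero(self, full_mask):
        vals = np.random.default_rng(0).standard_normal((full_mask.count(), 500))
        vals[0] = 3.0
        vmap = bold_variability_map(Timeseries4D(vals, full_mask, tr=1.0))
        got = vmap.in_mask(full_mask)
        assert got[0] == 0.0
        assert got[1] == pytest.approx(1.0, abs=0.15)  # unit-SD noise at n=500

    def test_variability_matches_loop(self, random_ts, full_mask):
        got = bold_variability_map(random_ts).in_mask(full_mask)
        for v in range(random_ts.n_voxels):
            assert got[v] == pytest.approx(np.std(random_ts.values[v]))

    def test_gs_covariance_identities(self, full_mask, rng):
        n = full_mask.count()
        vals = rng.standard_normal((n, 100))
        gs = vals.mean(axis=0)
        vals[0] = gs  # voxel equal to the global signal
        ts = Timeseries4D(vals, full_mask, tr=1.0)
        gs2 = ts.values.mean(axis=0)
        got = gs_covariance_map(ts).in_mask(full_mask)
        assert got[0] == pytest.approx(np.cov(ts.values[0], gs2, bias=True)[0, 1])
        for v in range(5):
            assert got[v] == pytest.approx(np.cov(ts.values[v], gs2, bias=True)[0, 1])

    def test_cr_sd_zero_and_identity(self, random_ts, full_mask):
        zero = random_ts.with_values(np.zeros_like(random_ts.values))
        assert np.all(cr_sd_map(zero).values == 0)
        assert np.allclose(
            cr_sd_map(random_ts).values, bold_variability_map(random_ts).values
        )


class TestThresholdTop:
    def test_keeps_ceil_fraction(self, full_mask, rng):
        n = full_mask.count()  # 144 voxels
        vmap = map_from_voxels(rng.standard_normal(n), full_mask)
        thr = threshold_top(vmap, full_mask, fraction=0.04)
        assert thr.count() == int(np.ceil(0.04 * n))

    def test_tie_break_by_voxel_index(self, full_mask):
        vmap = map_from_voxels(np.ones(full_mask.count()), full_mask)
        thr = threshold_top(vmap, full_mask, fraction=0.04)
        sel = thr.in_mask(full_mask).astype(bool)
        k = int(np.ceil(0.04 * full_mask.count()))
        assert np.array_equal(np.flatnonzero(sel), np.arange(k))

    def test_matches_sort_oracle(self, full_mask, rng):
        vals = rng.standard_normal(full_mask.count())
        for use_abs in (True, False):
            thr = threshold_top(map_from_voxels(vals, full_mask), full_mask,
                                fraction=0.1, use_absolute=use_abs)
            score = np.abs(vals) if use_abs else vals
            k = int(np.ceil(0.1 * vals.size))
            expected = set(np.argsort(-score, kind="stable")[:k].tolist())
            assert set(np.flatnonzero(thr.in_mask(full_mask))) == expected


class TestDice:
    def test_identical_masks_one(self, full_mask):
        assert dice(full_mask, full_mask) == 1.0

    def test_disjoint_masks_zero(self, grid):
        a = np.zeros(grid.shape, dtype=int)
        b = np.zeros(grid.shape, dtype=int)
        a[0], b[1] = 1, 1
        assert dice(VolumeMap(a, grid, kind="brain_mask"),
                    VolumeMap(b, grid, kind="brain_mask")) == 0.0

    def test_partial_overlap_value(self, grid):
        # |A| = |B| = 24 (one slab each), overlap 12 -> 2*12/48 = 0.5
        a = np.zeros(grid.shape, dtype=int)
        b = np.zeros(grid.shape, dtype=int)
        a[0:1], b[0:1, :, :2] = 1, 1
        b[1:2, :, :2] = 1
        av, bv = a.sum(), b.sum()
        inter = (a & b).sum()
        expected = 2 * inter / (av + bv)
        assert dice(VolumeMap(a, grid, kind="brain_mask"),
                    VolumeMap(b, grid, kind="brain_mask")) == pytest.approx(expected)

    def test_both_empty_defined_zero(self, grid):
        empty = VolumeMap(np.zeros(grid.shape, dtype=int), grid, kind="brain_mask")
        assert dice(empty, empty) == 0.0

    def test_symmetric(self, grid, rng):
        a = VolumeMap((rng.random(grid.shape) > 0.5).astype(int), grid, kind="brain_mask")
        b = VolumeMap((rng.random(grid.shape) > 0.5).astype(int), grid, kind="brain_mask")
        assert dice(a, b) == dice(b, a)


class TestNetworkSpecificity:
    def test_identical_maps_dice_one(self, full_mask, rng):
        vmap = map_from_voxels(rng.standard_normal(full_mask.count()), full_mask)
        assert network_specificity(vmap, vmap, full_mask) == 1.0

    def test_equals_manual_composition(self, full_mask, rng):
        from boldqc.correction import smooth_spatial

        a = map_from_voxels(rng.standard_normal(full_mask.count()), full_mask)
        b = map_from_voxels(rng.standard_normal(full_mask.count()), full_mask)
        got = network_specificity(a, b, full_mask, fwhm=0.3, fraction=0.1)
        sa = threshold_top(smooth_spatial(a, 0.3, full_mask), full_mask, 0.1)
        sb = threshold_top(smooth_spatial(b, 0.3, full_mask), full_mask, 0.1)
        assert got == dice(sa, sb)

    def test_noise_vs_compact_canonical_near_chance(self):
        from boldqc.phantom import make_phantom, PhantomConfig

        ph = make_phantom(PhantomConfig(), seed=0)
        canonical = ph.canonical_map(0)
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(50):
            noise_map = map_from_voxels(
                rng.standard_normal(ph.brain_mask.count()), ph.brain_mask
            )
            vals.append(network_specificity(noise_map, canonical, ph.brain_mask))
        assert np.mean(vals) <= 0.1


class TestTimecourseMetrics:
    def test_confound_correlation_identity(self, rng):
        tc = rng.standard_normal(100)
        assert confound_correlation(tc, tc[None]) == pytest.approx(1.0)

    def test_confound_correlation_mean_of_abs(self, rng):
        # construct confounds with known correlations 0.5 and -0.3
        n = 20000
        x = rng.standard_normal(n)
        a = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        b = -0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        got = confound_correlation(x, np.vstack([a, b]))
        r1 = abs(np.corrcoef(x, a)[0, 1])
        r2 = abs(np.corrcoef(x, b)[0, 1])
        assert got == pytest.approx((r1 + r2) / 2)
        assert got == pytest.approx(0.4, abs=0.02)

    def test_orthogonal_constructs_near_zero(self):
        t = np.arange(64.0)
        net = np.sin(2 * np.pi * 4 * t / 64)
        conf = np.cos(2 * np.pi * 4 * t / 64)
        assert confound_correlation(net, conf[None]) < 1e-10

    def test_category_mean_single_timecourse(self, rng):
        tc = rng.standard_normal(30)
        got = category_mean_timecourse(tc[None])
        assert np.allclose(got, np.abs(tc / np.linalg.norm(tc)))

    def test_category_mean_sign_invariant(self, rng):
        tc = rng.standard_normal(30)
        a = category_mean_timecourse(np.vstack([tc, -tc]))
        b = category_mean_timecourse(tc[None])
        assert np.allclose(a, b)

    def test_category_mean_matches_loop(self, rng):
        tcs = rng.standard_normal((4, 25))
        got = category_mean_timecourse(tcs)
        manual = np.mean([np.abs(t / np.linalg.norm(t)) for t in tcs], axis=0)
        assert np.allclose(got, manual)

    def test_network_amplitude_pythagorean(self, grid):
        vals = np.zeros(grid.shape)
        vals[0, 0, 0], vals[0, 0, 1] = 3.0, 4.0
        assert network_amplitude(VolumeMap(vals, grid)) == pytest.approx(5.0)

    def test_network_amplitude_zero_map(self, grid):
        assert network_amplitude(VolumeMap(np.zeros(grid.shape), grid)) == 0.0


class TestModifiedZOutliers:
    def test_all_equal_none_removed(self):
        assert np.array_equal(modified_z_outliers(np.full(10, 3.0)), np.arange(10))

    def test_planted_outlier_removed(self):
        values = np.array(list(range(1, 11)) + [100.0])
        kept = modified_z_outliers(values)
        assert np.array_equal(kept, np.arange(10))

    def test_formula_oracle(self, rng):
        values = rng.standard_normal(30)
        values[5] = 40.0
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        z = 0.6745 * (values - med) / mad
        first_pass = np.abs(z) > 3.5
        assert first_pass[5]
        kept = modified_z_outliers(values)
        assert 5 not in kept

    def test_two_tier_outliers_two_passes(self):
        # 11.0 is shielded by the huge outlier on pass one
        base = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 1.02, 0.98, 1.0, 1.01])
        values = np.concatenate([base, [11.0, 1000.0]])
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        assert abs(0.6745 * (11.0 - med) / mad) < 3.5 or mad > 0  # sanity
        kept = modified_z_outliers(values)
        assert 10 not in kept and 11 not in kept
        assert np.array_equal(kept, np.arange(10))


class TestScanInclusion:
    def test_good_record_kept(self):
        recs = [record(scan_id=f"s{i}") for i in range(5)]
        result = apply_scan_inclusion(recs)
        assert len(result.kept) == 5 and not result.excluded

    def test_exclusion_reasons(self):
        recs = [
            record("good"),
            record("low_dice", dice_=0.3),
            record("high_corr", corr=0.4),
            record("few_frames", ret=0.5),
        ]
        result = apply_scan_inclusion(recs)
        assert result.excluded["low_dice"] == "specificity"
        assert result.excluded["high_corr"] == "confound_correlation"
        assert result.excluded["few_frames"] == "retained_fraction"
        assert [r.scan_id for r in result.kept] == ["good"]

    def test_amplitude_outlier_removed(self):
        recs = [record(f"s{i}", amp=10.0 + 0.1 * i) for i in range(10)]
        recs.append(record("extreme", amp=500.0))
        result = apply_scan_inclusion(recs)
        assert result.excluded["extreme"] == "amplitude_outlier"
        assert len(result.kept) == 10


class TestGroupReport:
    def test_thresholds_not_applied_below_min_n(self):
        fix = make_fd_effect_group(n_scans=5, seed=0)
        rep = group_report(fix.scan_maps, fix.canonical, fix.records, fix.brain_mask,
                           min_n=8)
        assert not rep.thresholds_applied

    def test_linear_fd_effect_recovered(self):
        fix = make_fd_effect_group(n_scans=15, seed=0)
        rep = group_report(fix.scan_maps, fix.canonical, fix.records, fix.brain_mask)
        assert rep.thresholds_applied
        assert rep.mean_effects["mean_fd"] > 0.8
        assert rep.variability_dice > 0.8

    def test_exact_linear_relation_gives_r_one(self):
        fix = make_fd_effect_group(n_scans=10, seed=1, noise_sigma=0.0)
        rep = group_report(fix.scan_maps, fix.canonical, fix.records, fix.brain_mask)
        vox = rep.effect_maps["mean_fd"].in_mask(fix.brain_mask)
        canon_vox = fix.canonical.in_mask(fix.brain_mask)
        strong = canon_vox > 0.5
        assert np.allclose(np.abs(vox[strong]), 1.0, atol=1e-8)

    def test_permutation_null_stays_small(self):
        fix = make_fd_effect_group(n_scans=15, effect_gain=0.0, seed=2)
        rng = np.random.default_rng(3)
        fds = np.array([r.mean_fd for r in fix.records])
        hits = 0
        n_perm = 50
        for _ in range(n_perm):
            perm = rng.permutation(fds)
            recs = [dataclasses.replace(r, mean_fd=float(f))
                    for r, f in zip(fix.records, perm)]
            rep = group_report(fix.scan_maps, fix.canonical, recs, fix.brain_mask)
            if abs(rep.mean_effects["mean_fd"]) < 0.15:
                hits += 1
        assert hits >= 0.95 * n_perm


class TestDistributionReport:
    def test_single_scan_row(self):
        df = distribution_report([record("only")])
        assert len(df) == 1
        assert not df.filter(like="outlier_").to_numpy().any()

    def test_planted_extreme_fd_flagged(self):
        recs = [record(f"s{i}", fd=0.01 + 0.0005 * i) for i in range(12)]
        recs.append(record("mover", fd=5.0))
        df = distribution_report(recs)
        assert bool(df.loc[df.scan_id == "mover", "outlier_mean_fd"].iloc[0])
        assert not df.loc[df.scan_id != "mover", "outlier_mean_fd"].any()

    def test_csv_roundtrip(self, tmp_path):
        recs = [record(f"s{i}", amp=float(i)) for i in range(5)]
        df = distribution_report(recs)
        path = tmp_path / "dist.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert back.shape == df.shape
        assert np.allclose(back["amplitude_l2"], df["amplitude_l2"])
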