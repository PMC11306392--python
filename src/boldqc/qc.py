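"""Scan- and group-level quality control for network analysis.

Scan level: network specificity (Dice overlap of top-4% thresholded,
0.3 mm-smoothed scan vs canonical network maps), temporal correlation of
the network timecourse with confound-component timecourses, network
amplitude (L2 norm of the dual-regression beta map), and the retained-frame
rule. Group level: cross-scan variability of connectivity and its Dice
against the canonical network, plus voxelwise correlations of connectivity
with three confound measures (mean FD, confound-regression SD, temporal
degrees of freedom), summarised as the maximum absolute mean correlation
inside the thresholded canonical network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GroupQCReport,
    ScanQCRecord,
    Timeseries4D,
    VolumeMap,
    map_from_voxels,
)
from .correction import smooth_spatial

DEFAULT_TOP_FRACTION = 0.04
DEFAULT_QC_SMOOTH_FWHM_MM = 0.3
DEFAULT_DICE_MIN = 0.4
DEFAULT_CONFOUND_CORR_MAX = 0.25
DEFAULT_VARIABILITY_DICE_MIN = 0.38
DEFAULT_EFFECT_MAX = 0.25
DEFAULT_MIN_PASSING = 8
DEFAULT_MIN_RETAINED = 2.0 / 3.0
DEFAULT_MODIFIED_Z = 3.5


# ---------------------------------------------------------------------------
# voxelwise diagnostic maps


def bold_variability_map(ts: Timeseries4D) -> VolumeMap:
    """Temporal standard deviation at each voxel."""
    return map_from_voxels(ts.values.std(axis=1), ts.mask, kind="variability")


def gs_covariance_map(ts: Timeseries4D) -> VolumeMap:
    """Temporal covariance of each voxel with the global (brain-mean) signal."""
    gs = ts.values.mean(axis=0)
    gs_c = gs - gs.mean()
    v = ts.values - ts.values.mean(axis=1, keepdims=True)
    cov = v @ gs_c / ts.n_frames
    return map_from_voxels(cov, ts.mask, kind="covariance")


def cr_sd_map(y_cr: Timeseries4D) -> VolumeMap:
    """Voxelwise SD of the confound-predicted timeseries (variance modelled
    by confound regression)."""
    return map_from_voxels(y_cr.values.std(axis=1), y_cr.mask, kind="variability")


# ---------------------------------------------------------------------------
# thresholding, overlap, correlation metrics


def threshold_top(
    vmap: VolumeMap,
    brain_mask: VolumeMap,
    fraction: float = DEFAULT_TOP_FRACTION,
    use_absolute: bool = True,
) -> VolumeMap:
    """Binary map of the ceil(fraction * N_mask) in-mask voxels of highest
    (absolute, per flag) value; ties broken by voxel index for determinism."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    vals = vmap.in_mask(brain_mask).astype(float)
    score = np.abs(vals) if use_absolute else vals
    n_keep = int(np.ceil(fraction * score.size))
    # stable sort on (-score, index): highest first, earliest index wins ties
    order = np.argsort(-score, kind="stable")
    sel = np.zeros(score.size, dtype=bool)
    sel[order[:n_keep]] = True
    return map_from_voxels(sel.astype(float), brain_mask, kind="brain_mask")


def dice(a: VolumeMap, b: VolumeMap) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0 when both masks are empty."""
    if not a.grid.matches(b.grid):
        raise ValueError("grid mismatch between Dice inputs")
    av = np.asarray(a.values, dtype=bool)
    bv = np.asarray(b.values, dtype=bool)
    denom = av.sum() + bv.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(av, bv).sum() / denom)


def network_specificity(
    scan_map: VolumeMap,
    canonical_map: VolumeMap,
    brain_mask: VolumeMap,
    fwhm: float = DEFAULT_QC_SMOOTH_FWHM_MM,
    fraction: float = DEFAULT_TOP_FRACTION,
    use_absolute: bool = True,
) -> float:
    """Dice overlap of the smoothed, top-fraction-thresholded scan network
    map against the canonical map treated the same way."""
    sm_scan = smooth_spatial(scan_map, fwhm, brain_mask)
    sm_canon = smooth_spatial(canonical_map, fwhm, brain_mask)
    thr_scan = threshold_top(sm_scan, brain_mask, fraction, use_absolute)
    thr_canon = threshold_top(sm_canon, brain_mask, fraction, use_absolute)
    return dice(thr_scan, thr_canon)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def confound_correlation(network_tc: np.ndarray, confound_tcs: np.ndarray) -> float:
    """Mean absolute Pearson correlation of the network timecourse with each
    confound-component timecourse."""
    confound_tcs = np.atleast_2d(np.asarray(confound_tcs, dtype=float))
    if confound_tcs.shape[0] == 0:
        raise ValueError("need at least one confound timecourse")
    if confound_tcs.shape[1] != np.asarray(network_tc).size:
        raise ValueError("timecourse lengths differ")
    rs = [abs(_pearson(np.asarray(network_tc, dtype=float), tc)) for tc in confound_tcs]
    return float(np.mean(rs))


def category_mean_timecourse(tcs: np.ndarray) -> np.ndarray:
    """Representative timecourse of a component category: each timecourse is
    L2-normalised, absolute-valued, then averaged across components."""
    tcs = np.atleast_2d(np.asarray(tcs, dtype=float))
    if tcs.shape[0] == 0:
        raise ValueError("need at least one timecourse")
    norms = np.linalg.norm(tcs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return np.abs(tcs / norms).mean(axis=0)


def network_amplitude(amplitude_map: VolumeMap, brain_mask: Optional[VolumeMap] = None) -> float:
    """L2 norm of the network amplitude map over in-mask voxels."""
    if brain_mask is None:
        vals = np.asarray(amplitude_map.values, dtype=float).ravel()
    else:
        vals = amplitude_map.in_mask(brain_mask)
    return float(np.linalg.norm(vals))


# ---------------------------------------------------------------------------
# outlier removal and scan inclusion


def modified_z_outliers(values: np.ndarray, threshold: float = DEFAULT_MODIFIED_Z) -> np.ndarray:
    """Indices kept after iterative modified-z outlier removal.

    modified z = 0.6745 (x - median) / MAD on the remaining values; values
    with |z| > threshold are dropped and the statistic recomputed until no
    outlier remains. MAD = 0 terminates with no further removals.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values for outlier detection")
    kept = np.arange(values.size)
    while kept.size > 0:
        vals = values[kept]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad == 0:
            break
        z = 0.6745 * (vals - med) / mad
        bad = np.abs(z) > threshold
        if not bad.any():
            break
        kept = kept[~bad]
    return kept


@dataclass
class InclusionResult:
    kept: list[ScanQCRecord]
    excluded: dict  # scan_id -> reason


def apply_scan_inclusion(
    records: Sequence[ScanQCRecord],
    dice_min: float = DEFAULT_DICE_MIN,
    corr_max: float = DEFAULT_CONFOUND_CORR_MAX,
    min_retained: float = DEFAULT_MIN_RETAINED,
    z_threshold: float = DEFAULT_MODIFIED_Z,
) -> InclusionResult:
    """Scan-level inclusion: retained-frame rule, network-specificity and
    confound-correlation thresholds, then iterative amplitude-outlier
    removal on the survivors. Each exclusion carries its reason."""
    excluded: dict = {}
    survivors: list[ScanQCRecord] = []
    for rec in records:
        if rec.retained_fraction < min_retained:
            excluded[rec.scan_id] = "retained_fraction"
        elif rec.dice_specificity <= dice_min:
            excluded[rec.scan_id] = "specificity"
        elif rec.confound_correlation >= corr_max:
            excluded[rec.scan_id] = "confound_correlation"
        else:
            survivors.append(rec)
    if len(survivors) >= 3:
        amps = np.array([r.amplitude_l2 for r in survivors])
        kept_idx = set(modified_z_outliers(amps, z_threshold).tolist())
        final = []
        for i, rec in enumerate(survivors):
            if i in kept_idx:
                final.append(rec)
            else:
                excluded[rec.scan_id] = "amplitude_outlier"
        survivors = final
    return InclusionResult(kept=survivors, excluded=excluded)


# ---------------------------------------------------------------------------
# group statistical report


def _cross_scan_corr(conn: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Per-voxel Pearson r across scans between connectivity and a covariate.

    ``conn`` is (scan, voxel); ``covariate`` is (scan,) for scalar measures
    or (scan, voxel) for voxel-matched measures."""
    cov = np.asarray(covariate, dtype=float)
    c = conn - conn.mean(axis=0)
    c_sd = c.std(axis=0)
    if cov.ndim == 1:
        x = cov - cov.mean()
        x_sd = x.std()
        num = c.T @ x / conn.shape[0]
        denom = c_sd * x_sd
    else:
        x = cov - cov.mean(axis=0)
        x_sd = x.std(axis=0)
        num = (c * x).mean(axis=0)
        denom = c_sd * x_sd
    out = np.zeros(conn.shape[1])
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    return out


def group_report(
    scan_maps: Sequence[VolumeMap],
    canonical_map: VolumeMap,
    records: Sequence[ScanQCRecord],
    brain_mask: VolumeMap,
    min_n: int = DEFAULT_MIN_PASSING,
    dice_min: float = DEFAULT_DICE_MIN,
    corr_max: float = DEFAULT_CONFOUND_CORR_MAX,
    fwhm: float = DEFAULT_QC_SMOOTH_FWHM_MM,
    fraction: float = DEFAULT_TOP_FRACTION,
) -> GroupQCReport:
    """Group-level network variability and confound-effect report.

    When at least ``min_n`` scans pass scan-level inclusion, group measures
    are computed on the passers (thresholds_applied=True); otherwise on all
    scans, flagged accordingly. The variability map is the voxelwise
    cross-scan SD of connectivity, smoothed and top-fraction thresholded,
    compared with the canonical network by Dice. The three effect maps
    correlate connectivity across scans with mean FD (scalar), tDOF
    (scalar), and the confound-regression SD map (voxel-matched); the
    summary is the maximum absolute mean correlation inside the thresholded
    canonical network.
    """
    if len(scan_maps) < 2:
        raise ValueError("group report needs at least 2 scans")
    if len(scan_maps) != len(records):
        raise ValueError("one QC record per scan map required")
    for m in scan_maps:
        if not m.grid.matches(canonical_map.grid):
            raise ValueError("grid mismatch between scan maps and canonical map")

    inclusion = apply_scan_inclusion(records, dice_min=dice_min, corr_max=corr_max)
    passing_ids = {r.scan_id for r in inclusion.kept}
    n_passing = len(passing_ids)
    if n_passing >= min_n:
        sel = [i for i, r in enumerate(records) if r.scan_id in passing_ids]
        thresholds_applied = True
    else:
        sel = list(range(len(records)))
        thresholds_applied = False

    conn = np.stack([scan_maps[i].in_mask(brain_mask) for i in sel])  # (scan, voxel)
    recs = [records[i] for i in sel]

    variability = map_from_voxels(conn.std(axis=0), brain_mask, kind="variability")
    var_sm = smooth_spatial(variability, fwhm, brain_mask)
    var_thr = threshold_top(var_sm, brain_mask, fraction, use_absolute=False)
    canon_sm = smooth_spatial(canonical_map, fwhm, brain_mask)
    canon_thr = threshold_top(canon_sm, brain_mask, fraction, use_absolute=True)
    variability_dice = dice(var_thr, canon_thr)

    mean_fd = np.array([r.mean_fd for r in recs])
    tdof = np.array([r.tdof for r in recs], dtype=float)
    effect_maps: dict = {}
    mean_effects: dict = {}
    network_sel = canon_thr.in_mask(brain_mask).astype(bool)
    covariates: dict = {"mean_fd": mean_fd, "tdof": tdof}
    if all(r.cr_sd_map is not None for r in recs):
        covariates["cr_sd"] = np.stack([r.cr_sd_map.in_mask(brain_mask) for r in recs])
    for name, cov in covariates.items():
        r_vox = _cross_scan_corr(conn, cov)
        effect_maps[name] = map_from_voxels(r_vox, brain_mask, kind="connectivity")
        mean_effects[name] = float(r_vox[network_sel].mean())
    max_abs = float(max(abs(v) for v in mean_effects.values()))

    return GroupQCReport(
        variability_map=variability,
        variability_dice=variability_dice,
        effect_maps=effect_maps,
        mean_effects=mean_effects,
        max_abs_mean_effect=max_abs,
        n_passing=n_passing,
        thresholds_applied=thresholds_applied,
    )


# ---------------------------------------------------------------------------
# distribution report


def distribution_report(
    records: Sequence[ScanQCRecord],
    dice_min: float = DEFAULT_DICE_MIN,
    corr_max: float = DEFAULT_CONFOUND_CORR_MAX,
    z_threshold: float = DEFAULT_MODIFIED_Z,
) -> pd.DataFrame:
    """Per-scan table of quality metrics with per-metric outlier flags.

    Outliers (modified z > threshold) are evaluated on the subset of scans
    passing scan-level thresholds, after amplitude-outlier removal, for each
    metric independently.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "scan_id": r.scan_id,
                "dice_specificity": r.dice_specificity,
                "amplitude_l2": r.amplitude_l2,
                "confound_correlation": r.confound_correlation,
                "mean_fd": r.mean_fd,
                "mean_cr_sd": r.mean_cr_sd,
                "tdof": r.tdof,
                "retained_fraction": r.retained_fraction,
            }
        )
    df = pd.DataFrame(rows)
    metrics = ["amplitude_l2", "confound_correlation", "mean_fd", "mean_cr_sd", "tdof"]
    for m in metrics:
        df[f"outlier_{m}"] = False
    inclusion = apply_scan_inclusion(records, dice_min=dice_min, corr_max=corr_max,
                                     z_threshold=z_threshold)
    passing_ids = [r.scan_id for r in inclusion.kept]
    if len(passing_ids) >= 3:
        sub = df[df.scan_id.isin(passing_ids)]
        for m in metrics:
            vals = sub[m].to_numpy(dtype=float)
            if np.all(np.isfinite(vals)):
                kept = set(modified_z_outliers(vals, z_threshold).tolist())
                flag_ids = [sid for i, sid in enumerate(sub.scan_id) if i not in kept]
                df.loc[df.scan_id.isin(flag_ids), f"outlier_{m}"] = True
    df["passed_inclusion"] = df.scan_id.isin(passing_ids)
    return df
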