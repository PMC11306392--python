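"""Ordered confound-correction workflow for BOLD timeseries.

The steps, each optional except linear detrending, are applied strictly in
the sequence: frame censoring -> detrending -> ICA-based motion-component
removal -> (simulation of censored frames + Butterworth filtering + edge
trimming + re-censoring) -> confound regression -> intensity scaling
(+ optional voxelwise variance standardisation) -> spatial smoothing.
Censoring first keeps signal spikes from biasing the later fits; filtering
operates on a full-length series with censored frames simulated from the
Lomb-Scargle spectral estimate so the filter never sees missing data, and
the censoring mask is re-applied afterwards. Nuisance regressors receive
the same censoring, detrending and filtering as the data before the
voxelwise regression Y_hat = Y - X beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import (
    ConfoundMatrix,
    MotionParameters,
    ProcessingFlags,
    Timeseries4D,
    TemporalMask,
    VolumeMap,
    map_from_voxels,
    mask_indices,
)
from .regressors import (
    DEFAULT_HEAD_RADIUS_MM,
    RegressorSpec,
    acompcor,
    dvars as compute_dvars,
    framewise_displacement,
    motion_24,
    motion_6,
)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.3548


# ---------------------------------------------------------------------------
# censoring


def censor_fd(fd: np.ndarray, threshold: float) -> TemporalMask:
    """Censor frames whose FD exceeds ``threshold`` (mm), plus 1 preceding
    and 2 following frames; out-of-range neighbours are simply omitted."""
    if threshold <= 0:
        raise ValueError(f"FD censoring threshold must be positive, got {threshold}")
    fd = np.asarray(fd, dtype=float)
    n = fd.size
    keep = np.ones(n, dtype=bool)
    for t in np.flatnonzero(fd > threshold):
        keep[max(t - 1, 0): min(t + 3, n)] = False
    return TemporalMask(keep, n)


def censor_dvars_iterative(dvars_series: np.ndarray, z_threshold: float = 2.5) -> TemporalMask:
    """Iteratively z-score retained DVARS values and censor frames above
    ``z_threshold`` standard deviations, until a pass removes nothing.

    Frame 0 carries the artificial DVARS value 0 (no backward difference);
    it is excluded from the z-scoring population and never censored by it.
    """
    dvars_series = np.asarray(dvars_series, dtype=float)
    n = dvars_series.size
    if n < 3:
        raise ValueError("DVARS censoring needs at least 3 frames")
    keep = np.ones(n, dtype=bool)
    while True:
        idx = np.flatnonzero(keep)
        idx = idx[idx > 0]  # frame 0 excluded from the z population
        vals = dvars_series[idx]
        sd = vals.std()
        if sd == 0:
            break
        z = (vals - vals.mean()) / sd
        outliers = idx[z > z_threshold]
        if outliers.size == 0:
            break
        keep[outliers] = False
    return TemporalMask(keep, n)


# ---------------------------------------------------------------------------
# detrending


def _detrend_design(times: np.ndarray, order: int) -> np.ndarray:
    tc = times - times.mean()
    cols = [np.ones_like(tc), tc]
    if order == 2:
        cols.append(tc**2)
    return np.column_stack(cols)


def detrend(
    ts: Timeseries4D,
    mask: Optional[TemporalMask] = None,
    order: int = 1,
) -> tuple[Timeseries4D, np.ndarray]:
    """Remove per-voxel linear (or quadratic) trends by OLS on retained frames.

    The time regressor is mean-centered over the retained frames, so the
    fitted intercept equals the voxel's retained-frame mean — this intercept
    is returned and reused later for mean-based intensity scaling. The trend
    prediction is subtracted at *all* frames so the full-length series stays
    consistent for downstream simulation of censored frames.
    """
    if order not in (1, 2):
        raise ValueError(f"detrending order must be 1 or 2, got {order}")
    keep = mask.keep if mask is not None else np.ones(ts.n_frames, dtype=bool)
    n_ret = int(keep.sum())
    if n_ret <= order + 1:
        raise ValueError(f"detrending order {order} needs more than {order + 1} retained frames")
    times = np.arange(ts.n_frames, dtype=float) * ts.tr
    ret_times = times[keep]
    X = _detrend_design(ret_times, order)
    beta, *_ = np.linalg.lstsq(X, ts.values[:, keep].T, rcond=None)
    # evaluate the fitted trend at all frames, with the same centering
    tc_all = times - ret_times.mean()
    cols = [np.ones_like(tc_all), tc_all]
    if order == 2:
        cols.append(tc_all**2)
    X_all = np.column_stack(cols)
    trend = (X_all @ beta).T
    intercepts = beta[0].copy()
    return ts.with_values(ts.values - trend), intercepts


def detrend_columns(
    arr: np.ndarray, tr: float, keep: np.ndarray, order: int
) -> np.ndarray:
    """Detrend full-length regressor columns (frame, column) like the data."""
    times = np.arange(arr.shape[0], dtype=float) * tr
    ret_times = times[keep]
    X = _detrend_design(ret_times, order)
    beta, *_ = np.linalg.lstsq(X, arr[keep], rcond=None)
    tc_all = times - ret_times.mean()
    cols = [np.ones_like(tc_all), tc_all]
    if order == 2:
        cols.append(tc_all**2)
    return arr - np.column_stack(cols) @ beta


# ---------------------------------------------------------------------------
# Lomb-Scargle simulation of censored frames


def lombscargle_reconstruct(
    values: np.ndarray,
    times: np.ndarray,
    keep: np.ndarray,
    tr: float,
    oversampling: float = 4.0,
) -> np.ndarray:
    """Reconstruct full-length series from retained samples by summing the
    Lomb-Scargle per-frequency sinusoid estimates.

    ``values`` is (voxel, frame) full length; the reconstruction at retained
    frames is replaced by the observed values, and the simulated portion is
    rescaled so each voxel's reconstructed standard deviation matches the
    observed one (the spectral estimate alone underestimates broadband power).
    Deterministic given the data: no random phases are drawn.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.all():
        return values.copy()
    n_ret = int(keep.sum())
    if n_ret == 0:
        raise ValueError("cannot simulate censored frames with no retained frames")
    t_ret = times[keep]
    span = times[-1] - times[0]
    df = 1.0 / (span * oversampling)
    nyquist = 1.0 / (2.0 * tr)
    freqs = np.arange(df, nyquist + 0.5 * df, df)
    V = values[:, keep]
    means = V.mean(axis=1, keepdims=True)
    Vc = V - means
    obs_sd = Vc.std(axis=1)

    omega = 2.0 * np.pi * freqs  # (F,)
    # per-frequency time offset tau of the Lomb-Scargle formulation
    arg = np.outer(t_ret, 2.0 * omega)  # (n_ret, F)
    tau = np.arctan2(np.sin(arg).sum(axis=0), np.cos(arg).sum(axis=0)) / (2.0 * omega)
    ph_ret = np.outer(t_ret, omega) - omega * tau  # (n_ret, F)
    C = np.cos(ph_ret)
    S = np.sin(ph_ret)
    cc = (C**2).sum(axis=0)
    ss = (S**2).sum(axis=0)
    ss[ss == 0] = 1.0
    cc[cc == 0] = 1.0
    A = (Vc @ C) / cc  # (voxel, F) cosine amplitudes
    B = (Vc @ S) / ss

    ph_all = np.outer(times, omega) - omega * tau  # (n_frames, F)
    recon = A @ np.cos(ph_all).T + B @ np.sin(ph_all).T

    rec_sd = recon[:, keep].std(axis=1)
    scale = np.where(rec_sd > 0, obs_sd / np.where(rec_sd > 0, rec_sd, 1.0), 0.0)
    recon *= scale[:, None]
    recon += means
    recon[:, keep] = V
    return recon


def simulate_censored(
    ts: Timeseries4D, mask: TemporalMask, oversampling: float = 4.0
) -> Timeseries4D:
    """Fill censored frames with values simulated from the retained frames'
    Lomb-Scargle spectral estimate; retained frames keep their observed
    values exactly. With no censored frames the input is returned unchanged."""
    if mask.keep.all():
        return ts
    if mask.n_kept == 0:
        raise ValueError("no retained frames to estimate the spectrum from")
    times = np.arange(ts.n_frames, dtype=float) * ts.tr
    recon = lombscargle_reconstruct(ts.values, times, mask.keep, ts.tr, oversampling)
    return ts.with_values(recon)


# ---------------------------------------------------------------------------
# frequency filtering


def frequency_filter(
    ts: Timeseries4D,
    highpass: Optional[float] = None,
    lowpass: Optional[float] = None,
    order: int = 3,
    edge_trim_s: float = 30.0,
) -> tuple[Timeseries4D, TemporalMask]:
    """Zero-phase Butterworth filter per voxel, then trim
    ``floor(edge_trim_s / tr)`` frames at each end against edge ringing.

    Censored frames must have been simulated beforehand; the caller re-applies
    the censoring mask after filtering. Returns the filtered series and the
    edge-trim TemporalMask (full length; trimmed frames marked censored).
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    for name, cut in (("highpass", highpass), ("lowpass", lowpass)):
        if cut is not None and cut >= nyquist:
            raise ValueError(f"{name} cutoff {cut} Hz >= Nyquist {nyquist:.4f} Hz")
    n_trim = int(np.floor(edge_trim_s / ts.tr)) if (highpass or lowpass) else 0
    edge_keep = np.ones(ts.n_frames, dtype=bool)
    if n_trim > 0:
        edge_keep[:n_trim] = False
        edge_keep[ts.n_frames - n_trim:] = False
    edge_mask = TemporalMask(edge_keep, ts.n_frames)
    if highpass is None and lowpass is None:
        return ts, edge_mask
    if edge_keep.sum() < 3:
        raise ValueError("series too short for the requested edge trimming")
    if highpass is not None and lowpass is not None:
        sos = signal.butter(order, [highpass, lowpass], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    elif highpass is not None:
        sos = signal.butter(order, highpass, btype="highpass", fs=1.0 / ts.tr, output="sos")
    else:
        sos = signal.butter(order, lowpass, btype="lowpass", fs=1.0 / ts.tr, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values, axis=1)
    return ts.with_values(filtered), edge_mask


# ---------------------------------------------------------------------------
# confound regression (the central OLS model)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            continue
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        denom = np.linalg.norm(X[:, j])
        if denom == 0 or np.linalg.norm(resid) / denom < 1e-8:
            bad.append(names[j])
    return bad


def regress_confounds(
    ts: Timeseries4D, confounds: ConfoundMatrix
) -> tuple[Timeseries4D, Timeseries4D, np.ndarray]:
    """Voxelwise OLS removal of the nuisance design:
    beta = OLS(X, Y);  Y_CR = X beta;  Y_hat = Y - Y_CR.

    Returns (Y_hat, Y_CR, beta) with beta of shape (regressor, voxel).
    Residuals are orthogonal to every column of X.
    """
    X = confounds.to_array()
    if X.shape[0] != ts.n_frames:
        raise ValueError(
            f"confound matrix has {X.shape[0]} rows but timeseries has {ts.n_frames} frames"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, confounds.names)
        raise ValueError(f"rank-deficient confound matrix; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    y_cr = (X @ beta).T
    return ts.with_values(ts.values - y_cr), ts.with_values(y_cr), beta


# ---------------------------------------------------------------------------
# intensity scaling and variance standardisation

SCALING_METHODS = ("grand_mean", "voxelwise_mean", "global_sd", "voxelwise_z", "none")


def scale_intensity(
    ts: Timeseries4D,
    intercepts: Optional[np.ndarray] = None,
    method: str = "grand_mean",
) -> Timeseries4D:
    """Scale signal amplitude for between-scan comparability.

    grand_mean: divide by the brain-wide mean of the detrending intercepts
    and multiply by 100 (%BOLD). voxelwise_mean: same per voxel. global_sd:
    divide by the total SD across all in-mask voxel timeseries. voxelwise_z:
    divide each voxel by its own SD (zero-SD voxels are left as zeros).
    """
    if method == "none":
        return ts
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}")
    v = ts.values
    if method == "grand_mean":
        if intercepts is None:
            raise ValueError("grand_mean scaling needs the detrending intercepts")
        gm = float(np.mean(intercepts))
        if gm == 0:
            raise ValueError("zero grand mean; cannot scale")
        return ts.with_values(v * (100.0 / gm))
    if method == "voxelwise_mean":
        if intercepts is None:
            raise ValueError("voxelwise_mean scaling needs the detrending intercepts")
        denom = np.asarray(intercepts, dtype=float)
        if np.any(denom == 0):
            raise ValueError("zero voxel mean(s); cannot scale voxelwise")
        return ts.with_values(v * (100.0 / denom[:, None]))
    if method == "global_sd":
        total_sd = v.std()
        if total_sd == 0:
            raise ValueError("zero total standard deviation; cannot scale")
        return ts.with_values(v / total_sd)
    # voxelwise_z
    sd = v.std(axis=1)
    out = np.zeros_like(v)
    nz = sd > 0
    out[nz] = v[nz] / sd[nz, None]
    return ts.with_values(out)


def standardize_variance(ts: Timeseries4D) -> Timeseries4D:
    """Equalise voxelwise variance while conserving the total 4D SD.

    Each voxel is divided by its temporal SD, then the whole series is
    rescaled so the total SD over all in-mask values equals its pre-operation
    value. Distinct from z-scoring, which changes the overall scale.
    Zero-variance voxels are carried as zeros.
    """
    v = ts.values
    total_sd = v.std()
    if total_sd == 0:
        return ts
    sd = v.std(axis=1)
    nz = sd > 0
    out = np.zeros_like(v)
    out[nz] = v[nz] / sd[nz, None]
    new_total = out.std()
    if new_total > 0:
        out *= total_sd / new_total
    return ts.with_values(out)


# ---------------------------------------------------------------------------
# spatial smoothing


def _smooth_volume(vol: np.ndarray, mask: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    num = ndimage.gaussian_filter(np.where(mask, vol, 0.0), sigma=sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
    out = np.zeros_like(vol, dtype=float)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def smooth_spatial(obj, fwhm: float, brain_mask: Optional[VolumeMap] = None):
    """Per-frame 3D Gaussian smoothing with sigma = FWHM/2.3548 per axis in
    voxel units; the kernel is renormalised inside the brain mask so mass is
    conserved near the boundary. ``fwhm`` is in mm; 0 is the identity."""
    if fwhm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm == 0:
        return obj
    if isinstance(obj, Timeseries4D):
        mask3d = np.asarray(obj.mask.values, dtype=bool)
        sigma = fwhm / FWHM_TO_SIGMA / np.asarray(obj.grid.spacing)
        data = obj.to_4d()
        out = np.empty_like(data)
        for t in range(obj.n_frames):
            out[..., t] = _smooth_volume(data[..., t], mask3d, sigma)
        flat = out.reshape(-1, obj.n_frames)[mask_indices(obj.mask)]
        return obj.with_values(flat)
    if isinstance(obj, VolumeMap):
        if brain_mask is None:
            mask3d = np.ones(obj.grid.shape, dtype=bool)
        else:
            mask3d = np.asarray(brain_mask.values, dtype=bool)
        sigma = fwhm / FWHM_TO_SIGMA / np.asarray(obj.grid.spacing)
        vol = _smooth_volume(np.asarray(obj.values, dtype=float), mask3d, sigma)
        return VolumeMap(vol, obj.grid, kind=obj.kind)
    raise TypeError(f"cannot smooth object of type {type(obj)}")


# ---------------------------------------------------------------------------
# the orchestrated workflow


@dataclass
class WorkflowOptions:
    """Configuration for :func:`run_workflow`; defaults give the minimal
    non-optional workflow (linear detrending + grand-mean scaling)."""

    fd_censor_threshold: Optional[float] = None  # mm; the baseline preset is 0.05
    dvars_censor: bool = False
    dvars_z_threshold: float = 2.5
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    detrend_order: int = 1
    aroma: bool = False
    aroma_n_components: int = 8
    aroma_options: Optional[dict] = None  # thresholds/weights forwarded to the classifier
    highpass: Optional[float] = None  # Hz
    lowpass: Optional[float] = None  # Hz
    filter_order: int = 3
    edge_trim_s: float = 30.0
    lomb_scargle_oversampling: float = 4.0
    regressors: Optional[RegressorSpec] = None
    scaling: str = "grand_mean"
    variance_standardization: bool = False
    smoothing_fwhm: Optional[float] = None  # mm
    min_retained_fraction: float = 2.0 / 3.0
    seed: Optional[int] = None


@dataclass
class CorrectedScan:
    """Output bundle of the correction workflow (retained frames only)."""

    cleaned: Timeseries4D
    temporal_mask: TemporalMask  # final full-length keep flags (censor AND edge trim)
    censor_mask: TemporalMask  # censoring only, before edge trimming
    confounds: Optional[ConfoundMatrix]
    y_cr: Optional[Timeseries4D]
    beta: Optional[np.ndarray]
    intercepts: np.ndarray
    fd: np.ndarray
    dvars: np.ndarray
    tdof: int
    retained_fraction: float
    excluded: bool
    options: WorkflowOptions
    aroma_labels: Optional[list[str]] = None

    @property
    def frame_times(self) -> np.ndarray:
        return np.flatnonzero(self.temporal_mask.keep) * self.cleaned.tr


def _restrict(ts: Timeseries4D, keep: np.ndarray) -> Timeseries4D:
    return Timeseries4D(ts.values[:, keep], ts.mask, ts.tr, ts.space_tag)


def run_workflow(
    ts: Timeseries4D,
    mp: MotionParameters,
    options: Optional[WorkflowOptions] = None,
    wm_mask: Optional[VolumeMap] = None,
    csf_mask: Optional[VolumeMap] = None,
) -> CorrectedScan:
    """Run the full ordered confound-correction workflow on one scan."""
    opt = options or WorkflowOptions()
    if mp.n_frames != ts.n_frames:
        raise ValueError("motion parameters and timeseries frame counts differ")

    fd = framewise_displacement(mp, opt.head_radius_mm)
    dvars_series = compute_dvars(ts)

    # --- 1. frame censoring -------------------------------------------------
    censor = TemporalMask.all_kept(ts.n_frames)
    if opt.fd_censor_threshold is not None:
        censor = censor & censor_fd(fd, opt.fd_censor_threshold)
    if opt.dvars_censor:
        censor = censor & censor_dvars_iterative(dvars_series, opt.dvars_z_threshold)
    excluded = censor.retained_fraction < opt.min_retained_fraction
    if censor.n_kept <= opt.detrend_order + 1:
        raise ValueError("censoring left too few frames to detrend")

    # --- 2. detrending ------------------------------------------------------
    ts_dt, intercepts = detrend(ts, censor, opt.detrend_order)

    # --- 3. rodent ICA-AROMA ------------------------------------------------
    aroma_labels: Optional[list[str]] = None
    if opt.aroma:
        from .aroma import run_aroma  # local import to avoid a cycle

        retained = _restrict(ts_dt, censor.keep)
        cleaned_ret, aroma_labels = run_aroma(
            retained,
            mp.subset(censor),
            csf_mask=csf_mask,
            n_components=opt.aroma_n_components,
            seed=opt.seed,
            **(opt.aroma_options or {}),
        )
        full = ts_dt.values.copy()
        full[:, censor.keep] = cleaned_ret.values
        ts_dt = ts_dt.with_values(full)

    # --- 4. simulation + frequency filtering + re-censoring -----------------
    do_filter = opt.highpass is not None or opt.lowpass is not None
    if do_filter:
        ts_sim = simulate_censored(ts_dt, censor, opt.lomb_scargle_oversampling)
        ts_filt, edge_mask = frequency_filter(
            ts_sim, opt.highpass, opt.lowpass, opt.filter_order, opt.edge_trim_s
        )
    else:
        ts_filt, edge_mask = ts_dt, TemporalMask.all_kept(ts.n_frames)
    final_mask = censor & edge_mask  # the censoring mask is re-applied
    if final_mask.n_kept < 3:
        raise ValueError("fewer than 3 frames retained after censoring and edge trimming")
    y = _restrict(ts_filt, final_mask.keep)

    # --- 5. confound regression ---------------------------------------------
    confounds: Optional[ConfoundMatrix] = None
    y_cr: Optional[Timeseries4D] = None
    beta: Optional[np.ndarray] = None
    n_reg = 0
    if opt.regressors is not None and opt.regressors.any_requested():
        confounds = _build_processed_regressors(
            opt, mp, y, ts.n_frames, ts.tr, censor, final_mask, wm_mask, csf_mask
        )
        confounds.check_no_zero_columns()
        y, y_cr, beta = regress_confounds(y, confounds)
        n_reg = confounds.n_regressors

    # --- 6. intensity scaling ------------------------------------------------
    y = scale_intensity(y, intercepts, opt.scaling)
    if y_cr is not None:
        y_cr = scale_intensity(y_cr, intercepts, opt.scaling)

    # --- 7. variance standardisation -----------------------------------------
    if opt.variance_standardization:
        y = standardize_variance(y)

    # --- 8. spatial smoothing -------------------------------------------------
    if opt.smoothing_fwhm:
        y = smooth_spatial(y, opt.smoothing_fwhm)

    tdof = final_mask.n_kept - n_reg - opt.detrend_order - 1
    return CorrectedScan(
        cleaned=y,
        temporal_mask=final_mask,
        censor_mask=censor,
        confounds=confounds,
        y_cr=y_cr,
        beta=beta,
        intercepts=intercepts,
        fd=fd,
        dvars=dvars_series,
        tdof=tdof,
        retained_fraction=censor.retained_fraction,
        excluded=excluded,
        options=opt,
        aroma_labels=aroma_labels,
    )


def _build_processed_regressors(
    opt: WorkflowOptions,
    mp: MotionParameters,
    y: Timeseries4D,
    n_frames: int,
    tr: float,
    censor: TemporalMask,
    final_mask: TemporalMask,
    wm_mask: Optional[VolumeMap],
    csf_mask: Optional[VolumeMap],
) -> ConfoundMatrix:
    """Assemble regressors with the same censoring/detrending/filtering as
    the data: motion-derived columns are built full length and pushed through
    the identical temporal operations; tissue-signal columns are extracted
    from the already-processed data itself."""
    spec = opt.regressors
    assert spec is not None
    frames: list[pd.DataFrame] = []
    if spec.mot24 or spec.mot6:
        motion_df = motion_24(mp) if spec.mot24 else motion_6(mp)
        arr = motion_df.to_numpy(dtype=float)
        arr = detrend_columns(arr, tr, censor.keep, opt.detrend_order)
        if opt.highpass is not None or opt.lowpass is not None:
            times = np.arange(n_frames, dtype=float) * tr
            arr = lombscargle_reconstruct(
                arr.T, times, censor.keep, tr, opt.lomb_scargle_oversampling
            ).T
            nyq = 1.0 / (2.0 * tr)
            if opt.highpass is not None and opt.lowpass is not None:
                sos = signal.butter(opt.filter_order, [opt.highpass, opt.lowpass],
                                    btype="bandpass", fs=1.0 / tr, output="sos")
            elif opt.highpass is not None:
                sos = signal.butter(opt.filter_order, opt.highpass,
                                    btype="highpass", fs=1.0 / tr, output="sos")
            else:
                sos = signal.butter(opt.filter_order, opt.lowpass,
                                    btype="lowpass", fs=1.0 / tr, output="sos")
            arr = signal.sosfiltfilt(sos, arr, axis=0)
        frames.append(pd.DataFrame(arr[final_mask.keep], columns=motion_df.columns))
    # tissue-derived columns come from the processed data (already censored,
    # detrended and filtered), so they carry the same temporal state
    if spec.wm_signal:
        if wm_mask is None:
            raise ValueError("WM signal regression requires a WM mask")
        sel = wm_mask.in_mask(y.mask).astype(bool)
        if not sel.any():
            raise ValueError("empty WM mask within the brain mask")
        frames.append(pd.DataFrame({"wm_signal": y.values[sel].mean(axis=0)}))
    if spec.csf_signal:
        if csf_mask is None:
            raise ValueError("CSF signal regression requires a CSF mask")
        sel = csf_mask.in_mask(y.mask).astype(bool)
        if not sel.any():
            raise ValueError("empty CSF mask within the brain mask")
        frames.append(pd.DataFrame({"csf_signal": y.values[sel].mean(axis=0)}))
    if spec.global_signal:
        frames.append(pd.DataFrame({"global_signal": y.values.mean(axis=0)}))
    if spec.acompcor:
        comps = acompcor(y, wm_mask, csf_mask, spec.n_acompcor)
        frames.append(pd.DataFrame(comps, columns=[f"acompcor_{i}" for i in range(comps.shape[1])]))
    df = pd.concat([f.reset_index(drop=True) for f in frames], axis=1)
    flags = ProcessingFlags(
        censored=True,
        detrended=True,
        filtered=opt.highpass is not None or opt.lowpass is not None,
    )
    return ConfoundMatrix(df, processing_flags=flags)
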