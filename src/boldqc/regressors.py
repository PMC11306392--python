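"""Nuisance timecourses: framewise displacement, DVARS, motion/tissue regressors.

Framewise displacement follows the Power convention — the sum of absolute
backward differences of the six rigid parameters, rotations converted to arc
length at a configurable head radius (default 5 mm, a rodent-scale head).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ConfoundMatrix,
    MotionParameters,
    ProcessingFlags,
    Timeseries4D,
    VolumeMap,
)

DEFAULT_HEAD_RADIUS_MM = 5.0


def framewise_displacement(mp: MotionParameters, radius: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Per-frame head displacement in mm; FD[0] = 0 by convention."""
    if radius <= 0:
        raise ValueError(f"head radius must be positive, got {radius}")
    if mp.n_frames < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    d_trans = np.abs(np.diff(mp.translations, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(mp.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + radius * d_rot])
    return fd


def dvars(ts: Timeseries4D) -> np.ndarray:
    """Root-mean-square over in-mask voxels of the backward temporal difference.

    DVARS[0] = 0 and should be excluded from downstream z-scoring.
    """
    if ts.n_frames < 2:
        raise ValueError("DVARS needs at least 2 frames")
    diffs = np.diff(ts.values, axis=1)
    series = np.sqrt(np.mean(diffs**2, axis=0))
    return np.concatenate([[0.0], series])


def motion_6(mp: MotionParameters) -> pd.DataFrame:
    return pd.DataFrame(mp.values, columns=list(MotionParameters.COLUMNS))


def motion_24(mp: MotionParameters) -> pd.DataFrame:
    """Friston-style expansion: 6 parameters, backward-difference derivatives,
    and the squares of both (24 columns; the 6 raw parameters come first)."""
    base = motion_6(mp)
    deriv = base.diff().fillna(0.0)
    deriv.columns = [f"{c}_deriv" for c in base.columns]
    sq = base**2
    sq.columns = [f"{c}_sq" for c in base.columns]
    deriv_sq = deriv**2
    deriv_sq.columns = [f"{c}_sq" for c in deriv.columns]
    return pd.concat([base, deriv, sq, deriv_sq], axis=1)


def _mask_mean(ts: Timeseries4D, tissue: VolumeMap) -> np.ndarray:
    sel = tissue.in_mask(ts.mask).astype(bool)
    if not sel.any():
        raise ValueError(f"empty tissue mask ({tissue.kind}) within the brain mask")
    return ts.values[sel].mean(axis=0)


def acompcor(ts: Timeseries4D, wm_mask: Optional[VolumeMap], csf_mask: Optional[VolumeMap],
             n_components: int = 5) -> np.ndarray:
    """First principal components of the combined WM+CSF voxel timeseries.

    The tissue voxels must already carry the same censoring/detrending as the
    data (``ts`` is expected to be the processed timeseries). Components are
    returned unit-normed and mutually orthogonal, shape (frame, n_components).
    """
    sel = np.zeros(ts.n_voxels, dtype=bool)
    for tissue in (wm_mask, csf_mask):
        if tissue is not None:
            sel |= tissue.in_mask(ts.mask).astype(bool)
    if not sel.any():
        raise ValueError("aCompCor requires a non-empty WM and/or CSF mask")
    if ts.n_frames < n_components + 1:
        raise ValueError(
            f"aCompCor with {n_components} components needs more than "
            f"{n_components + 1} retained frames, have {ts.n_frames}"
        )
    tissue_ts = ts.values[sel]  # (voxel, frame)
    tissue_ts = tissue_ts - tissue_ts.mean(axis=1, keepdims=True)
    # temporal principal components = left singular vectors of (frame, voxel)
    u, s, _ = np.linalg.svd(tissue_ts.T, full_matrices=False)
    comps = u[:, :n_components]
    # sign convention: positive loading sum, for reproducibility
    signs = np.sign(comps.sum(axis=0))
    signs[signs == 0] = 1.0
    return comps * signs


@dataclass
class RegressorSpec:
    """Which nuisance columns to assemble for confound regression."""

    mot6: bool = True
    mot24: bool = False
    wm_signal: bool = False
    csf_signal: bool = False
    global_signal: bool = False
    acompcor: bool = False
    n_acompcor: int = 5

    def any_requested(self) -> bool:
        return any([self.mot6, self.mot24, self.wm_signal, self.csf_signal,
                    self.global_signal, self.acompcor])


def build_regressors(
    spec: RegressorSpec,
    mp: Optional[MotionParameters],
    ts: Optional[Timeseries4D] = None,
    wm_mask: Optional[VolumeMap] = None,
    csf_mask: Optional[VolumeMap] = None,
    flags: Optional[ProcessingFlags] = None,
) -> ConfoundMatrix:
    """Assemble the nuisance design matrix from the requested sources.

    ``mp`` and ``ts`` must be at the same temporal state (same frames, same
    censoring) so that all columns align with the data entering regression.
    """
    cols: list[pd.DataFrame] = []
    if spec.mot24:
        if mp is None:
            raise ValueError("mot24 requested without motion parameters")
        cols.append(motion_24(mp))
    elif spec.mot6:
        if mp is None:
            raise ValueError("mot6 requested without motion parameters")
        cols.append(motion_6(mp))
    if spec.wm_signal:
        if ts is None or wm_mask is None:
            raise ValueError("WM signal regression requires the timeseries and a WM mask")
        cols.append(pd.DataFrame({"wm_signal": _mask_mean(ts, wm_mask)}))
    if spec.csf_signal:
        if ts is None or csf_mask is None:
            raise ValueError("CSF signal regression requires the timeseries and a CSF mask")
        cols.append(pd.DataFrame({"csf_signal": _mask_mean(ts, csf_mask)}))
    if spec.global_signal:
        if ts is None:
            raise ValueError("global signal regression requires the timeseries")
        cols.append(pd.DataFrame({"global_signal": ts.values.mean(axis=0)}))
    if spec.acompcor:
        if ts is None:
            raise ValueError("aCompCor requires the timeseries")
        comps = acompcor(ts, wm_mask, csf_mask, spec.n_acompcor)
        cols.append(pd.DataFrame(comps, columns=[f"acompcor_{i}" for i in range(comps.shape[1])]))
    if not cols:
        raise ValueError("no regressors requested")
    df = pd.concat([c.reset_index(drop=True) for c in cols], axis=1)
    return ConfoundMatrix(df, processing_flags=flags or ProcessingFlags())
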