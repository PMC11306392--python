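"""Connectivity analyses: seed maps, parcel matrices, dual regression.

Dual regression maps a set of group-level spatial priors (networks and
confound sources together) onto a single scan in two OLS stages: prior maps
regressed against each frame give one timecourse per component; those
timecourses — variance-normalised so the beta maps carry amplitude — are
then regressed against each voxel to give scan-specific spatial maps.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .core import (
    ComponentSet,
    Timeseries4D,
    VolumeMap,
    map_from_voxels,
)


def _pearson_map(ts: Timeseries4D, ref: np.ndarray) -> np.ndarray:
    ref = ref - ref.mean()
    ref_sd = ref.std()
    if ref_sd == 0:
        raise ValueError("reference timecourse has zero variance")
    v = ts.values - ts.values.mean(axis=1, keepdims=True)
    sd = v.std(axis=1)
    num = v @ ref / ts.n_frames
    out = np.zeros(ts.n_voxels)
    nz = sd > 0
    out[nz] = num[nz] / (sd[nz] * ref_sd)
    return out


def seed_connectivity(ts: Timeseries4D, seed: VolumeMap) -> VolumeMap:
    """Pearson r of every in-mask voxel with the mean seed timecourse."""
    sel = seed.in_mask(ts.mask).astype(bool)
    if not sel.any():
        raise ValueError("seed mask is empty within the brain mask")
    seed_tc = ts.values[sel].mean(axis=0)
    r = _pearson_map(ts, seed_tc)
    return map_from_voxels(r, ts.mask, kind="connectivity")


def parcel_timecourses(
    ts: Timeseries4D, parcellation: VolumeMap
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean timecourse per parcel (label > 0), ordered by label.

    Returns (labels, timecourses) with timecourses of shape (parcel, frame).
    Empty parcels are dropped with a warning.
    """
    labels_vox = parcellation.in_mask(ts.mask)
    labels = np.unique(labels_vox)
    labels = labels[labels > 0]
    kept, tcs = [], []
    for lab in labels:
        sel = labels_vox == lab
        if not sel.any():  # pragma: no cover - unique() guarantees presence
            continue
        kept.append(lab)
        tcs.append(ts.values[sel].mean(axis=0))
    all_labels = np.unique(np.asarray(parcellation.values))
    missing = set(all_labels[all_labels > 0]) - set(kept)
    if missing:
        warnings.warn(f"empty parcel(s) dropped: {sorted(missing)}")
    return np.asarray(kept), np.asarray(tcs)


def connectivity_matrix(ts: Timeseries4D, parcellation: VolumeMap) -> tuple[np.ndarray, np.ndarray]:
    """Pearson cross-correlation of all parcel mean timecourses.

    Returns (labels, matrix); the matrix is symmetric with unit diagonal.
    """
    labels, tcs = parcel_timecourses(ts, parcellation)
    if labels.size < 2:
        raise ValueError("need at least 2 non-empty parcels")
    mat = np.corrcoef(tcs)
    np.fill_diagonal(mat, 1.0)
    return labels, mat


def dual_regression(
    ts: Timeseries4D, priors: ComponentSet
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage OLS mapping of group priors onto one scan.

    Stage 1 regresses the prior maps (plus intercept) against each frame,
    yielding a timecourse per component. Stage 2 scales those timecourses
    to unit SD and regresses them (plus intercept) against each voxel,
    yielding beta maps whose scale carries network amplitude.

    Returns (timecourses, amplitude_maps): shapes (component, frame) and
    (component, voxel) in the shared voxel ordering.
    """
    if priors.maps.shape[1] != ts.n_voxels:
        raise ValueError("prior maps are not on the data grid / voxel ordering")
    n_comp = priors.n_components
    A = np.column_stack([priors.maps.T, np.ones(ts.n_voxels)])  # (voxel, C+1)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("collinear prior maps")
    b1, *_ = np.linalg.lstsq(A, ts.values, rcond=None)  # (C+1, frame)
    timecourses = b1[:n_comp]

    sd = timecourses.std(axis=1)
    if np.any(sd == 0):
        # a zero timecourse (e.g. zero data) yields zero maps for it
        norm_tcs = np.where(sd[:, None] > 0, timecourses / np.where(sd[:, None] > 0, sd[:, None], 1.0), 0.0)
    else:
        norm_tcs = timecourses / sd[:, None]
    X = np.column_stack([norm_tcs.T, np.ones(ts.n_frames)])  # (frame, C+1)
    nonzero = sd > 0
    if nonzero.any():
        Xnz = np.column_stack([norm_tcs[nonzero].T, np.ones(ts.n_frames)])
        if np.linalg.matrix_rank(Xnz) < Xnz.shape[1]:
            raise ValueError("collinear dual-regression timecourses")
        b2, *_ = np.linalg.lstsq(Xnz, ts.values.T, rcond=None)  # (Cnz+1, voxel)
        maps = np.zeros((n_comp, ts.n_voxels))
        maps[nonzero] = b2[:-1]
    else:
        maps = np.zeros((n_comp, ts.n_voxels))
    return timecourses, maps


def group_ica(
    scans: Sequence[Timeseries4D], n_components: int, seed: Optional[int] = None
) -> ComponentSet:
    """Temporal concatenation of corrected scans in common space followed by
    spatial ICA (pluggable backend; FastICA by default). Labels start as
    'other' for manual or config-driven assignment."""
    from .aroma import fastica_decompose

    if not scans:
        raise ValueError("no scans supplied")
    first = scans[0]
    for s in scans[1:]:
        if not s.grid.matches(first.grid) or s.n_voxels != first.n_voxels:
            raise ValueError("all scans must share one grid and mask")
    values = np.concatenate([s.values for s in scans], axis=1)
    if n_components > values.shape[1]:
        raise ValueError(
            f"{n_components} components requested but only {values.shape[1]} total frames"
        )
    concat = Timeseries4D(values, first.mask, first.tr, first.space_tag)
    return fastica_decompose(concat, n_components, seed)


def consensus_map(maps: Sequence[VolumeMap]) -> VolumeMap:
    """Voxelwise median across scans — the canonical-map construction."""
    if len(maps) < 2:
        raise ValueError("consensus needs at least 2 maps")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.matches(grid):
            raise ValueError("grid mismatch among consensus inputs")
    stack = np.stack([np.asarray(m.values, dtype=float) for m in maps])
    return VolumeMap(np.median(stack, axis=0), grid, kind="canonical")
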