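"""Domain types for masked BOLD timeseries and derived maps.

All voxel-indexed arrays in the package share one voxel ordering: the
C-order raveled indices of the ``True`` voxels of the brain mask. A
:class:`Timeseries4D` therefore stores a dense ``(n_voxels, n_frames)``
array rather than the full 4D volume, and any :class:`VolumeMap` on the
same grid can be flattened to that ordering with :meth:`VolumeMap.in_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

VOLUME_KINDS = frozenset(
    {
        "brain_mask",
        "csf_mask",
        "wm_mask",
        "edge_mask",
        "seed",
        "parcellation",
        "connectivity",
        "variability",
        "covariance",
        "canonical",
    }
)


@dataclass(frozen=True)
class Grid:
    """Sampling grid of a volume: 3D shape, voxel spacing (mm) and affine."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError(f"grid shape must be 3D, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        object.__setattr__(self, "affine", aff)

    def matches(self, other: "Grid", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )

    @classmethod
    def isotropic(cls, shape: Sequence[int], spacing_mm: float) -> "Grid":
        aff = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
        return cls(tuple(int(s) for s in shape), (spacing_mm,) * 3, aff)


def _check_same_grid(a: Grid, b: Grid, what: str) -> None:
    if not a.matches(b):
        raise ValueError(f"grid mismatch: {what}")


@dataclass
class VolumeMap:
    """A scalar map over a 3D grid (mask, seed, parcellation, statistic...)."""

    values: np.ndarray
    grid: Grid
    kind: str = "connectivity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"map shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.kind not in VOLUME_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.kind.endswith("_mask"):
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"{self.kind} must be binary, found values {uniq[:5]}")
            self.values = self.values.astype(bool)
        elif self.kind == "parcellation":
            vals = self.values
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.allclose(vals, np.round(vals)):
                    raise ValueError("parcellation labels must be integers")
                vals = np.round(vals).astype(int)
            if vals.min() < 0:
                raise ValueError("parcellation labels must be non-negative")
            self.values = vals

    def in_mask(self, mask: "VolumeMap") -> np.ndarray:
        """Flatten to the shared voxel ordering of ``mask`` (C-order raveled)."""
        _check_same_grid(self.grid, mask.grid, "map vs mask")
        idx = mask_indices(mask)
        return self.values.reshape(-1)[idx]

    def count(self) -> int:
        return int(np.count_nonzero(self.values))


def mask_indices(mask: VolumeMap) -> np.ndarray:
    """Raveled (C-order) indices of in-mask voxels — the package voxel order."""
    return np.flatnonzero(np.asarray(mask.values, dtype=bool).reshape(-1, order="C"))


def map_from_voxels(values: np.ndarray, mask: VolumeMap, kind: str = "connectivity",
                    fill: float = 0.0) -> VolumeMap:
    """Scatter a voxel-ordered vector back into a 3D map (fill outside mask)."""
    values = np.asarray(values, dtype=float)
    flat = np.full(int(np.prod(mask.grid.shape)), fill, dtype=float)
    flat[mask_indices(mask)] = values
    return VolumeMap(flat.reshape(mask.grid.shape), mask.grid, kind=kind)


@dataclass
class Timeseries4D:
    """Masked voxel x frame BOLD array with grid and repetition time.

    ``values[v, t]`` is the intensity of in-mask voxel ``v`` (C-order raveled
    mask index) at frame ``t``; raw scanner units on input, %BOLD (or
    SD units) after intensity scaling.
    """

    values: np.ndarray
    mask: VolumeMap
    tr: float
    space_tag: str = "commonspace"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("timeseries values must be (voxel, frame)")
        if self.tr <= 0:
            raise ValueError(f"repetition time must be positive, got {self.tr}")
        if self.n_frames < 3:
            raise ValueError(f"need at least 3 frames, got {self.n_frames}")
        if self.values.shape[0] != self.mask.count():
            raise ValueError(
                f"{self.values.shape[0]} voxel rows but mask has {self.mask.count()} voxels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("in-mask timeseries values must be finite")

    @property
    def grid(self) -> Grid:
        return self.mask.grid

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "Timeseries4D":
        return Timeseries4D(values, self.mask, self.tr, self.space_tag)

    def to_4d(self, fill: float = 0.0) -> np.ndarray:
        """Scatter back to a full (x, y, z, t) array."""
        out = np.full(self.grid.shape + (self.n_frames,), fill, dtype=float)
        flat = out.reshape(-1, self.n_frames)
        flat[mask_indices(self.mask)] = self.values
        return out


@dataclass
class TemporalMask:
    """Per-frame keep/censor flags; composition of two masks is logical AND."""

    keep: np.ndarray
    n_original: int = 0

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.n_original == 0:
            self.n_original = self.keep.size
        if self.keep.size != self.n_original:
            raise ValueError("temporal mask length must equal original frame count")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def retained_fraction(self) -> float:
        return self.n_kept / self.n_original

    def compose(self, other: "TemporalMask") -> "TemporalMask":
        if other.n_original != self.n_original:
            raise ValueError("cannot compose temporal masks of different lengths")
        return TemporalMask(self.keep & other.keep, self.n_original)

    def __and__(self, other: "TemporalMask") -> "TemporalMask":
        return self.compose(other)

    @classmethod
    def all_kept(cls, n_frames: int) -> "TemporalMask":
        return cls(np.ones(n_frames, dtype=bool), n_frames)


@dataclass
class MotionParameters:
    """Per-frame rigid-body motion: 3 translations (mm) + 3 rotations (rad)."""

    values: np.ndarray

    COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(
                f"motion parameters must have 6 columns, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]

    def subset(self, mask: TemporalMask) -> "MotionParameters":
        return MotionParameters(self.values[mask.keep])


@dataclass
class ProcessingFlags:
    """Temporal operations already applied to a set of nuisance timecourses."""

    censored: bool = False
    detrended: bool = False
    filtered: bool = False


@dataclass
class ConfoundMatrix:
    """Frames x regressors nuisance design (the X of the regression model)."""

    columns: "object"  # pandas.DataFrame, kept loose to avoid import cycle
    processing_flags: ProcessingFlags = field(default_factory=ProcessingFlags)

    def __post_init__(self) -> None:
        import pandas as pd

        if not isinstance(self.columns, pd.DataFrame):
            self.columns = pd.DataFrame(np.asarray(self.columns, dtype=float))

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.columns.columns]

    @property
    def n_frames(self) -> int:
        return self.columns.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.columns.shape[1]

    def to_array(self) -> np.ndarray:
        return self.columns.to_numpy(dtype=float)

    def check_no_zero_columns(self) -> None:
        arr = self.to_array()
        dead = [n for n, col in zip(self.names, arr.T) if np.allclose(col, 0)]
        if dead:
            raise ValueError(f"constant-zero regressor column(s) after processing: {dead}")


COMPONENT_LABELS = ("network", "confound", "other")


@dataclass
class ComponentSet:
    """Spatial components (maps + optional timecourses) with category labels."""

    maps: np.ndarray  # (component, voxel) in the shared voxel ordering
    mask: VolumeMap
    timecourses: Optional[np.ndarray] = None  # (component, frame)
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.maps.shape[1] != self.mask.count():
            raise ValueError("component maps must match brain-mask voxel count")
        if self.timecourses is not None:
            self.timecourses = np.atleast_2d(np.asarray(self.timecourses, dtype=float))
            if self.timecourses.shape[0] != self.n_components:
                raise ValueError("one timecourse per component required")
        if self.labels is None:
            self.labels = ["other"] * self.n_components
        if len(self.labels) != self.n_components:
            raise ValueError("labels must cover all components")
        bad = set(self.labels) - set(COMPONENT_LABELS)
        if bad:
            raise ValueError(f"unknown component label(s) {bad}; use {COMPONENT_LABELS}")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def select(self, label: str) -> np.ndarray:
        """Indices of components carrying the given label."""
        return np.array([i for i, l in enumerate(self.labels) if l == label], dtype=int)


@dataclass
class ScanQCRecord:
    """Scan-level quality metrics feeding inclusion decisions."""

    scan_id: str
    dice_specificity: float
    confound_correlation: float
    amplitude_l2: float
    mean_fd: float
    tdof: int
    retained_fraction: float
    cr_sd_map: Optional[VolumeMap] = None
    mean_cr_sd: float = float("nan")


@dataclass
class GroupQCReport:
    """Group-level network variability and confound-effect summary."""

    variability_map: VolumeMap
    variability_dice: float
    effect_maps: dict  # {"mean_fd": VolumeMap, "cr_sd": VolumeMap, "tdof": VolumeMap}
    mean_effects: dict  # mean r within the thresholded canonical network
    max_abs_mean_effect: float
    n_passing: int
    thresholds_applied: bool
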