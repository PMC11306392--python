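"""Readers and writers: NIfTI-1 volumes/timeseries, CSV tables, motion tables.

Round-trips are lossless within float32 precision; parcellations are
preserved exactly as integers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Grid, MotionParameters, Timeseries4D, VolumeMap, mask_indices

PathLike = Union[str, Path]


def _grid_from_img(img: nib.Nifti1Image) -> Grid:
    zooms = img.header.get_zooms()[:3]
    return Grid(tuple(img.shape[:3]), tuple(float(z) for z in zooms), np.asarray(img.affine))


def read_map(path: PathLike, kind: str = "connectivity") -> VolumeMap:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {img.ndim}D")
    data = np.asarray(img.dataobj)
    if kind == "parcellation":
        data = np.round(np.asarray(data, dtype=float)).astype(int)
    return VolumeMap(data, _grid_from_img(img), kind=kind)


def write_map(vmap: VolumeMap, path: PathLike) -> None:
    if vmap.kind == "parcellation" or vmap.kind.endswith("_mask"):
        data = np.asarray(vmap.values, dtype=np.int16)
    else:
        data = np.asarray(vmap.values, dtype=np.float32)
    nib.save(nib.Nifti1Image(data, vmap.grid.affine), str(path))


def read_timeseries(
    path: PathLike,
    mask: VolumeMap,
    tr: Optional[float] = None,
    space_tag: str = "commonspace",
) -> Timeseries4D:
    """Load a 4D NIfTI and extract in-mask voxel timecourses.

    TR precedence: explicit ``tr`` override, then the NIfTI header pixdim[4].
    Rodent headers frequently carry a wrong or zero TR, hence the override.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {img.ndim}D")
    grid = _grid_from_img(img)
    if not grid.matches(mask.grid):
        raise ValueError(f"{path}: image grid does not match the provided mask grid")
    if tr is None:
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if header_tr <= 0:
            raise ValueError(
                f"{path}: NIfTI header has no usable TR; pass an explicit override"
            )
        tr = header_tr
    data = np.asarray(img.dataobj, dtype=float)
    values = data.reshape(-1, data.shape[3])[mask_indices(mask)]
    return Timeseries4D(values, mask, tr=tr, space_tag=space_tag)


def write_timeseries(ts: Timeseries4D, path: PathLike) -> None:
    data = ts.to_4d().astype(np.float32)
    img = nib.Nifti1Image(data, ts.grid.affine)
    img.header.set_zooms(ts.grid.spacing + (ts.tr,))
    nib.save(img, str(path))


def read_motion(path: PathLike, rotations_in_degrees: bool = False) -> MotionParameters:
    """Parse a 6-column motion table (CSV or whitespace-delimited, optional header).

    Column order: 3 translations (mm) then 3 rotations (radians, or degrees
    with ``rotations_in_degrees=True``).
    """
    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    sep = "," if "," in first else r"\s+"
    has_header = False
    if first:
        cells = [c for c in (first.split(",") if sep == "," else first.split())]
        for cell in cells:
            try:
                float(cell)
            except ValueError:
                has_header = True
                break
    try:
        df = pd.read_csv(
            _io.StringIO(text),
            sep=sep,
            header=0 if has_header else None,
            engine="python",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: could not parse motion table: {exc}") from exc
    # an unnamed index column (e.g. pandas to_csv default) is dropped
    if df.shape[1] == 7 and has_header and str(df.columns[0]).startswith("Unnamed"):
        df = df.iloc[:, 1:]
    if df.shape[1] != 6:
        raise ValueError(f"{path}: motion table must have 6 columns, found {df.shape[1]}")
    values = df.to_numpy(dtype=float)
    if rotations_in_degrees:
        values = values.copy()
        values[:, 3:] = np.deg2rad(values[:, 3:])
    return MotionParameters(values)


def write_motion(mp: MotionParameters, path: PathLike) -> None:
    pd.DataFrame(mp.values, columns=list(MotionParameters.COLUMNS)).to_csv(path, index=False)


def write_table(rows: Iterable[dict], path: PathLike, columns: Optional[list[str]] = None) -> None:
    """Write record rows as CSV; an empty record list yields a header-only file."""
    rows = list(rows)
    if rows:
        df = pd.DataFrame(rows)
        if columns is not None:
            df = df[columns]
    else:
        df = pd.DataFrame(columns=columns or [])
    df.to_csv(path, index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
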