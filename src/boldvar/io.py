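"""NIfTI and TSV input/output.

Voxel time series live on a compact 3-D grid: the analysis mask is a 3-D
volume whose nonzero voxels, taken in C order, define the flat voxel index
used everywhere else in the package.  TR is stored in the 4th pixdim of the
NIfTI header.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .components import BehaviorTable
from .signalprep import SDMap, VoxelTimeSeries


def grid_shape(n_voxels: int) -> tuple[int, int, int]:
    """Near-cubic 3-D shape holding at least ``n_voxels`` voxels."""
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    nz = int(np.ceil(n_voxels / (side * side)))
    return (side, side, nz)


def grid_mask(n_voxels: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask volume with exactly ``n_voxels`` in-mask voxels + affine."""
    shape = grid_shape(n_voxels)
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    flat[:n_voxels] = True
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # nominal 3-mm isotropic grid
    return flat.reshape(shape), affine


def save_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, img.affine


def save_series(
    path: str | Path, ts: VoxelTimeSeries, mask: np.ndarray, affine: np.ndarray
) -> None:
    """Embed a voxels x timepoints matrix into a 4-D NIfTI via the mask."""
    if int(mask.sum()) != ts.n_voxels:
        raise ValueError("mask size does not match number of voxels")
    vol = np.zeros(mask.shape + (ts.n_timepoints,), dtype=np.float32)
    vol[mask, :] = ts.values.astype(np.float32)
    img = nib.Nifti1Image(vol, affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = ts.tr_seconds
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_series(
    path: str | Path,
    mask: np.ndarray,
    subject_id: str = "",
    occasion: int = 1,
) -> VoxelTimeSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D NIfTI")
    tr = float(img.header.get_zooms()[3])
    values = data[mask, :]
    return VoxelTimeSeries(
        values=values,
        tr_seconds=tr,
        voxel_ids=np.arange(values.shape[0]),
        subject_id=subject_id,
        occasion=occasion,
    )


def save_map(path: str | Path, values: np.ndarray, mask: np.ndarray, affine: np.ndarray) -> None:
    """Write a per-voxel statistic (SD map, BSR map, labels) as 3-D NIfTI."""
    vol = np.zeros(mask.shape, dtype=np.float32)
    vol[mask] = np.asarray(values, dtype=np.float32)
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def load_map(path: str | Path, mask: np.ndarray) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64)[mask]


def save_sd_map(path: str | Path, sd: SDMap, mask: np.ndarray, affine: np.ndarray) -> None:
    save_map(path, sd.values, mask, affine)


def save_behavior_table(path: str | Path, table: BehaviorTable) -> None:
    table.data.to_csv(path, sep="\t", index=True)


def save_indicator_metadata(path: str | Path, table: BehaviorTable) -> None:
    meta = pd.DataFrame(
        {
            "indicator": list(table.data.columns),
            "domain": [table.domains[c] for c in table.data.columns],
            "direction": [table.directions[c] for c in table.data.columns],
        }
    )
    meta.to_csv(path, sep="\t", index=False)


def load_indicator_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_behavior_table(
    path: str | Path, metadata: pd.DataFrame, occasion: str = "T1"
) -> BehaviorTable:
    data = pd.read_csv(path, sep="\t", index_col="subject_id")
    domains = dict(zip(metadata["indicator"], metadata["domain"]))
    directions = dict(zip(metadata["indicator"], metadata["direction"]))
    return BehaviorTable(data=data, domains=domains, directions=directions, occasion=occasion)
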