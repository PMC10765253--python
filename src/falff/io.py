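"""NIfTI-1, TSV, JSON and YAML input/output for the analysis modules.

4D BOLD volumes are flattened to a voxels-by-time matrix; the voxel ordering
(C order over the 3D grid) and affine are carried in a :class:`GridInfo` so
derived maps can be written back onto the original grid.  ROI label volumes
travel with a JSON sidecar mapping integer labels to region names and naming
the reference label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .roi import RoiSet
from .spectral import BandSpec, TimeSeriesGrid

__all__ = [
    "GridInfo",
    "load_band",
    "load_bold",
    "load_participants",
    "load_rois",
    "save_bold",
    "save_map",
    "save_participants",
    "save_rois",
]

DEFAULT_VOXEL_MM = 2.4


@dataclass
class GridInfo:
    """3D grid shape and affine needed to unflatten voxelwise vectors."""

    shape: tuple[int, int, int]
    affine: np.ndarray


def _identity_affine(voxel_mm: float = DEFAULT_VOXEL_MM) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    return affine


def load_bold(path: str | Path, tr: float | None = None) -> tuple[TimeSeriesGrid, GridInfo]:
    """Read a 4D NIfTI-1 BOLD volume as a voxels-by-time grid.

    The repetition time comes from the header's 4th zoom unless overridden.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise DataError(f"expected a 4D volume, got shape {data.shape}")
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    grid = TimeSeriesGrid(data.reshape(-1, data.shape[3]), tr)
    return grid, GridInfo(data.shape[:3], np.asarray(img.affine))


def save_bold(
    ts: TimeSeriesGrid, info: GridInfo | None, path: str | Path
) -> None:
    """Write a voxels-by-time grid as 4D NIfTI-1, recording the TR."""
    if info is None:
        info = GridInfo((ts.n_voxels, 1, 1), _identity_affine())
    data = ts.values.reshape(*info.shape, ts.n_timepoints).astype(np.float32)
    img = nib.Nifti1Image(data, info.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], ts.tr))
    nib.save(img, str(path))


def save_map(values: np.ndarray, info: GridInfo, path: str | Path) -> None:
    """Write a voxelwise map (e.g. fALFF or z-scores) as 3D NIfTI-1."""
    data = np.asarray(values, dtype=np.float32).reshape(info.shape)
    nib.save(nib.Nifti1Image(data, info.affine), str(path))


def save_rois(rois: RoiSet, info: GridInfo, path: str | Path) -> None:
    """Write a label volume plus its ``.json`` name/reference sidecar."""
    path = Path(path)
    data = rois.labels.reshape(info.shape).astype(np.int16)
    nib.save(nib.Nifti1Image(data, info.affine), str(path))
    sidecar = {
        "labels": {str(k): v for k, v in rois.names.items()},
        "reference": int(rois.reference_label),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_rois(path: str | Path) -> tuple[RoiSet, GridInfo]:
    """Read a label volume and its JSON sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata()).astype(int)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    names = {int(k): v for k, v in sidecar["labels"].items()}
    rois = RoiSet(labels.ravel(), names, int(sidecar["reference"]))
    return rois, GridInfo(labels.shape, np.asarray(img.affine))


def load_band(path: str | Path) -> BandSpec:
    """Read a band config: ``band: {low: 0.0, high: 0.1164}``."""
    cfg = yaml.safe_load(Path(path).read_text())
    band = cfg["band"] if "band" in cfg else cfg
    return BandSpec(float(band["low"]), float(band["high"]))


def load_participants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_participants(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
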