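"""Reference-ROI standardisation of fALFF maps and regional aggregation.

fALFF maps are z-scored within participant against a reference region
(frontal grey matter, an anterior-circulation territory): the reference mean
is subtracted and the result divided by the reference standard deviation.
Standardised maps are then averaged within named anatomical regions to give
one value per participant and region for group-level modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateReferenceError
from .spectral import AmplitudeMap

__all__ = ["RoiSet", "ZScoreMap", "regional_means", "zscore_against_reference"]


@dataclass
class RoiSet:
    """Integer region labels over a flattened voxel grid.

    ``labels`` assigns each voxel an integer label (0 = background);
    ``names`` maps labels to region names; ``reference_label`` marks the
    standardisation region, which must contain at least 2 voxels.
    """

    labels: np.ndarray
    names: dict[int, str]
    reference_label: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.reference_label not in self.names:
            raise DataError(
                f"reference label {self.reference_label} has no name entry"
            )
        if int((self.labels == self.reference_label).sum()) < 2:
            raise DataError(
                f"reference region {self.reference_label} needs >= 2 voxels"
            )
        present = set(np.unique(self.labels).tolist())
        missing = [lab for lab in self.names if lab not in present]
        if missing:
            raise DataError(f"named labels absent from the volume: {missing}")

    def voxels(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @property
    def region_names(self) -> list[str]:
        """Names of the non-reference regions, in label order."""
        return [
            self.names[lab]
            for lab in sorted(self.names)
            if lab != self.reference_label
        ]


@dataclass
class ZScoreMap:
    """Voxelwise fALFF standardised against the reference region.

    The standardisation constants actually used are carried along so the map
    is auditable; over the reference voxels the values have mean 0 and
    (sample) standard deviation 1 by construction.
    """

    values: np.ndarray
    reference_mean: float
    reference_sd: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.reference_sd > 0:
            raise DegenerateReferenceError("reference sd must be positive")


def zscore_against_reference(amap: AmplitudeMap, rois: RoiSet) -> ZScoreMap:
    """Standardise a fALFF map against the reference region.

    z(v) = (fALFF(v) - mean over reference voxels) / sd over reference voxels.
    The sample (n-1) standard deviation is used.  Undefined (NaN) fALFF voxels
    propagate as NaN; NaNs inside the reference region are excluded from the
    constants.
    """
    values = np.asarray(amap.values, dtype=float).ravel()
    if values.shape != rois.labels.shape:
        raise DataError(
            f"map has {values.size} voxels but labels have {rois.labels.size}"
        )
    ref = values[rois.labels == rois.reference_label]
    ref = ref[np.isfinite(ref)]
    if ref.size < 2:
        raise DegenerateReferenceError("reference region has < 2 defined voxels")
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if not sd > 0:
        raise DegenerateReferenceError("reference region has zero variance")
    return ZScoreMap((values - mean) / sd, mean, sd)


def regional_means(
    z: ZScoreMap, rois: RoiSet, participant_id: str
) -> pd.DataFrame:
    """Mean z-score per named region for one participant.

    Returns one row per named region (reference included) with columns
    ``participant_id, region, mean_z, n_voxels``.  Missing voxels are
    excluded from the mean; a region with no defined voxels keeps its row
    with ``mean_z = NaN`` and ``n_voxels = 0`` rather than being dropped.
    """
    rows = []
    for label in sorted(rois.names):
        region_values = z.values[rois.labels == label]
        defined = region_values[np.isfinite(region_values)]
        rows.append(
            {
                "participant_id": participant_id,
                "region": rois.names[label],
                "mean_z": float(defined.mean()) if defined.size else np.nan,
                "n_voxels": int(defined.size),
            }
        )
    return pd.DataFrame(rows)
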