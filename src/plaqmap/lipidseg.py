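"""Threshold segmentation of plaque lipid on a T2 map.

A voxel is classified as lipid when it lies inside the vessel-wall mask, its
T2 fit converged, and the fitted T2 is strictly below the threshold
(42 ms by default, the validated lipid cut-off).  Areas and volumes are
quantified voxel-wise: one voxel is one unit of in_plane^2 mm^2 per slice,
times the slice thickness for volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import VoxelGeometry
from .t2map import T2Map

__all__ = [
    "LIPID_T2_THRESHOLD_MS",
    "RoiMaskSet",
    "LipidMask",
    "segment_lipid",
    "slice_areas",
]

LIPID_T2_THRESHOLD_MS = 42.0


@dataclass
class RoiMaskSet:
    """Vessel-wall (and optional lumen) masks on the image grid."""

    wall: np.ndarray
    lumen: np.ndarray | None = None
    geometry: VoxelGeometry = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wall = np.asarray(self.wall, dtype=bool)
        if self.geometry is None:
            self.geometry = VoxelGeometry()
        if self.lumen is not None:
            self.lumen = np.asarray(self.lumen, dtype=bool)
            if self.lumen.shape != self.wall.shape:
                raise ValueError("lumen and wall masks must share a grid")
            if np.any(self.wall & self.lumen):
                raise ValueError("wall and lumen masks must be disjoint")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.wall.shape


@dataclass
class LipidMask:
    """Boolean lipid classification, a subset of the wall mask."""

    mask: np.ndarray
    threshold_ms: float
    geometry: VoxelGeometry
    source: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


def segment_lipid(
    t2map: T2Map,
    rois: RoiMaskSet,
    threshold_ms: float = LIPID_T2_THRESHOLD_MS,
    source: str = "",
) -> LipidMask:
    """Classify lipid voxels: wall AND converged AND t2 < threshold (strict).

    Non-converged voxels are never lipid; a fitted T2 exactly at the
    threshold is fibrous.
    """
    if threshold_ms <= 0:
        raise ValueError("threshold_ms must be positive")
    if rois.shape != t2map.t2.shape:
        raise ValueError(
            f"ROI grid {rois.shape} does not match T2 map grid {t2map.t2.shape}"
        )
    with np.errstate(invalid="ignore"):
        below = t2map.t2 < threshold_ms
    mask = rois.wall & t2map.converged & below
    return LipidMask(
        mask=mask, threshold_ms=float(threshold_ms), geometry=rois.geometry,
        source=source,
    )


def slice_areas(lipid: LipidMask, rois: RoiMaskSet) -> pd.DataFrame:
    """Per-slice lipid and wall areas, volumes and lipid percentage.

    Returns a table with one row per slice: voxel counts, mm^2 areas
    (count * in_plane^2), mm^3 volumes (area * slice thickness) and the lipid
    percentage ``100 * lipid voxels / wall voxels``.  Slices without wall
    voxels get NaN lipid percentage and ``wall_empty`` set.
    """
    if rois.shape != lipid.shape:
        raise ValueError("lipid mask and ROI grids do not match")
    geom = lipid.geometry
    lipid_vox = lipid.mask.sum(axis=(0, 1)).astype(float)
    wall_vox = rois.wall.sum(axis=(0, 1)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(wall_vox > 0, 100.0 * lipid_vox / wall_vox, np.nan)
    return pd.DataFrame(
        {
            "slice": np.arange(lipid.shape[2]),
            "lipid_voxels": lipid_vox,
            "lipid_mm2": lipid_vox * geom.voxel_area_mm2,
            "wall_voxels": wall_vox,
            "wall_mm2": wall_vox * geom.voxel_area_mm2,
            "lipid_pct": pct,
            "lipid_mm3": lipid_vox * geom.voxel_volume_mm3,
            "wall_mm3": wall_vox * geom.voxel_volume_mm3,
            "wall_empty": wall_vox == 0,
        }
    )
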