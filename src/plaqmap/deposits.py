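"""Connected lipid deposits and the lipid-distribution indices.

Deposits are 2-D connected components of the lipid mask within each slice
(no merging across slices).  Components whose area is at most 1% of the
slice's pre-exclusion lipid area are excluded as noise, in a single pass;
percentages of the retained deposits are then taken over the retained total.

Indices on a slice with ``n`` retained deposits:

* ``LLD%`` -- the largest deposit's percentage of the retained lipid area;
* ``RLD%`` -- the mean percentage of the remaining deposits,
  ``100 * (1 - LLD%/100) / (n - 1)``, defined for ``n >= 2``;
* ``LAI = LLD% / RLD%`` -- the lipid aggregation index: high for one
  coalesced pool, low for scattered uniform deposits.  Undefined (NaN) for
  slices with fewer than two retained deposits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import VoxelGeometry
from .lipidseg import LipidMask, RoiMaskSet, slice_areas

__all__ = [
    "label_deposits",
    "apply_small_exclusion",
    "deposit_table",
    "lld_percent",
    "rld_percent",
    "lai",
    "slice_metrics",
    "VesselMetrics",
    "vessel_summary",
    "SMALL_DEPOSIT_FRACTION",
]

# deposits with area <= this fraction of the slice's pre-exclusion lipid
# area are treated as noise (inclusive boundary)
SMALL_DEPOSIT_FRACTION = 0.01

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_deposits(slice_mask: np.ndarray, connectivity: int = 8):
    """Label maximal connected components of a 2-D boolean slice.

    Labels are assigned deterministically in raster order of each
    component's first voxel (label 1 = component whose first voxel comes
    first in row-major order).

    Returns
    -------
    labels : int ndarray, same shape
    areas : float ndarray, shape (n_components,)
        Voxel count of component ``i + 1``.
    """
    slice_mask = np.asarray(slice_mask, dtype=bool)
    if slice_mask.ndim != 2:
        raise ValueError("label_deposits expects a 2-D slice mask")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(slice_mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return labels, np.empty(0)
    # enforce raster order of first occurrence
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.intp)
    nz = np.nonzero(flat)[0]
    # reversed so the earliest index wins
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[labels]
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(float)
    return labels, areas


def apply_small_exclusion(
    areas: np.ndarray,
    slice_index: int = 0,
    connectivity: int = 8,
    voxel_area_mm2: float = VoxelGeometry().voxel_area_mm2,
) -> pd.DataFrame:
    """Mark deposits at or below 1% of the pre-exclusion slice lipid as noise.

    The denominator of the 1% rule is the pre-exclusion total; the pass is
    applied once (no re-testing after renormalisation).  ``area_pct`` of the
    retained deposits is computed over the retained total and therefore sums
    to 100 within each slice that keeps at least one deposit; excluded
    deposits get NaN.
    """
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("component areas must be positive")
    total = areas.sum()
    retained = areas > SMALL_DEPOSIT_FRACTION * total
    ret_total = areas[retained].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(retained, 100.0 * areas / ret_total, np.nan)
    return pd.DataFrame(
        {
            "slice": slice_index,
            "label": np.arange(1, len(areas) + 1),
            "area_voxels": areas,
            "area_mm2": areas * voxel_area_mm2,
            "area_pct": pct,
            "retained": retained,
            "connectivity": connectivity,
        }
    )


def deposit_table(
    lipid: LipidMask,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Label and classify deposits on every slice of a lipid mask volume."""
    frames = []
    for s in range(lipid.shape[2]):
        _, areas = label_deposits(lipid.mask[:, :, s], connectivity)
        if len(areas):
            frames.append(
                apply_small_exclusion(
                    areas, s, connectivity, lipid.geometry.voxel_area_mm2
                )
            )
    if not frames:
        return apply_small_exclusion(np.empty(0), 0, connectivity).iloc[:0]
    return pd.concat(frames, ignore_index=True)


def _retained(table: pd.DataFrame) -> np.ndarray:
    return table.loc[table["retained"], "area_voxels"].to_numpy(dtype=float)


def lld_percent(table: pd.DataFrame) -> float:
    """Largest retained deposit as a percentage of the retained lipid area.

    NaN when the slice keeps no deposits (undefined).
    """
    areas = _retained(table)
    if len(areas) == 0:
        return float("nan")
    return float(100.0 * areas.max() / areas.sum())


def rld_percent(table: pd.DataFrame) -> float:
    """Mean percentage of the non-largest retained deposits.

    ``100 * (1 - LLD%/100) / (n - 1)``; NaN (undefined) when fewer than two
    deposits are retained.
    """
    areas = _retained(table)
    n = len(areas)
    if n < 2:
        return float("nan")
    lld_frac = areas.max() / areas.sum()
    return float(100.0 * (1.0 - lld_frac) / (n - 1))


def lai(table: pd.DataFrame) -> float:
    """Lipid aggregation index, ``LLD% / RLD%``.

    Algebraically ``lld_frac * (n - 1) / (1 - lld_frac)``.  NaN (undefined)
    when fewer than two deposits are retained.
    """
    r = rld_percent(table)
    if not np.isfinite(r):
        return float("nan")
    return float(lld_percent(table) / r)


def slice_metrics(
    lipid: LipidMask,
    rois: RoiMaskSet,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Per-slice lipid quantification plus distribution indices.

    Combines :func:`plaqmap.lipidseg.slice_areas` with per-slice deposit
    labeling, the <=1% exclusion and the LLD%/RLD%/LAI indices.
    """
    out = slice_areas(lipid, rois)
    deps = deposit_table(lipid, connectivity)
    n_ret, lld_v, rld_v, lai_v = [], [], [], []
    for s in range(lipid.shape[2]):
        sub = deps[deps["slice"] == s]
        n_ret.append(int(sub["retained"].sum()))
        lld_v.append(lld_percent(sub))
        rld_v.append(rld_percent(sub))
        lai_v.append(lai(sub))
    out["n_deposits_retained"] = n_ret
    out["lld_pct"] = lld_v
    out["rld_pct"] = rld_v
    out["lai"] = lai_v
    return out


@dataclass
class VesselMetrics:
    """Vessel-level aggregation over the studied slices.

    Volumes are the per-slice means over all studied slices (the vessel-level
    unit of analysis); the maximal-lipid slice is the argmax of slice lipid
    volume with ties broken toward the lowest slice index.
    """

    n_slices: int
    mean_lipid_mm3: float
    mean_wall_mm3: float
    mean_lipid_pct: float
    max_slice: int | None
    max_slice_lipid_pct: float
    max_slice_lld_pct: float
    max_slice_rld_pct: float
    max_slice_lai: float
    max_slice_n_deposits: int
    bifurcation_slice: int | None
    bifurcation_is_max: bool


def vessel_summary(
    metrics: pd.DataFrame,
    bifurcation_slice: int | None = None,
) -> VesselMetrics:
    """Aggregate per-slice metrics to the vessel level.

    Slices flagged ``wall_empty`` are dropped from the means.  When every
    slice is lipid-free the maximal-lipid slice and its indices are
    undefined (None/NaN) and lipid means are zero.
    """
    valid = metrics[~metrics["wall_empty"]]
    if len(valid) == 0:
        raise ValueError("no slice has wall voxels; vessel summary undefined")
    lipid_vol = valid["lipid_mm3"].to_numpy()
    if np.all(lipid_vol == 0):
        max_slice = None
        max_row = None
    else:
        max_slice = int(valid["slice"].iloc[int(np.argmax(lipid_vol))])
        max_row = valid[valid["slice"] == max_slice].iloc[0]
    return VesselMetrics(
        n_slices=int(len(valid)),
        mean_lipid_mm3=float(valid["lipid_mm3"].mean()),
        mean_wall_mm3=float(valid["wall_mm3"].mean()),
        mean_lipid_pct=float(valid["lipid_pct"].mean()),
        max_slice=max_slice,
        max_slice_lipid_pct=float(max_row["lipid_pct"]) if max_row is not None else float("nan"),
        max_slice_lld_pct=float(max_row["lld_pct"]) if max_row is not None else float("nan"),
        max_slice_rld_pct=float(max_row["rld_pct"]) if max_row is not None else float("nan"),
        max_slice_lai=float(max_row["lai"]) if max_row is not None else float("nan"),
        max_slice_n_deposits=int(max_row["n_deposits_retained"]) if max_row is not None else 0,
        bifurcation_slice=bifurcation_slice,
        bifurcation_is_max=(
            max_slice is not None
            and bifurcation_slice is not None
            and max_slice == bifurcation_slice
        ),
    )
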