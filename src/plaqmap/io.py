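"""NIfTI and TSV input/output.

Multi-echo stacks are stored either as a single 4-D NIfTI (echo along the
4th axis) with a JSON sidecar listing the echo times, or as a directory of
per-echo 3-D NIfTI volumes plus an ``echo_times.tsv``.  Both dialects are
read transparently.  All volumes of one vessel share the same axis-aligned
affine built from the voxel geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import MultiEchoStack, VoxelGeometry
from .t2map import T2Map

__all__ = [
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "write_t2map",
    "read_t2map",
    "write_table",
    "read_table",
]


def _geometry_from_affine(affine: np.ndarray) -> VoxelGeometry:
    # round away float32 header noise (NIfTI stores the affine in float32)
    zooms = np.round(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)), 6)
    if not np.isclose(zooms[0], zooms[1]):
        raise ValueError("anisotropic in-plane voxels are not supported")
    return VoxelGeometry(in_plane=float(zooms[0]), slice_thickness=float(zooms[2]))


def write_volume(volume: np.ndarray, path, geometry: VoxelGeometry | None = None) -> None:
    """Write a 3-D volume (float or boolean) as NIfTI."""
    if geometry is None:
        geometry = VoxelGeometry()
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, geometry.affine()), str(path))


def read_volume(path) -> tuple[np.ndarray, VoxelGeometry]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), _geometry_from_affine(img.affine)


def write_stack(stack: MultiEchoStack, path, mode: str = "4d") -> None:
    """Write a multi-echo stack.

    ``mode="4d"``: single NIfTI at ``path`` (echo = 4th axis) plus a JSON
    sidecar ``<path stem>_echoes.json`` with the echo times in ms.
    ``mode="echoes"``: directory ``path`` with ``echo_000.nii.gz`` ... and
    ``echo_times.tsv``.
    """
    path = Path(path)
    affine = stack.geometry.affine()
    if mode == "4d":
        vol4d = np.moveaxis(stack.data, 0, -1)
        nib.save(nib.Nifti1Image(vol4d, affine), str(path))
        sidecar = path.parent / (path.name.split(".")[0] + "_echoes.json")
        sidecar.write_text(json.dumps({"echo_times_ms": list(stack.echo_times)}))
    elif mode == "echoes":
        path.mkdir(parents=True, exist_ok=True)
        for e in range(stack.n_echoes):
            nib.save(
                nib.Nifti1Image(stack.data[e], affine),
                str(path / f"echo_{e:03d}.nii.gz"),
            )
        pd.DataFrame(
            {"echo": np.arange(stack.n_echoes), "te_ms": stack.echo_times}
        ).to_csv(path / "echo_times.tsv", sep="\t", index=False)
    else:
        raise ValueError("mode must be '4d' or 'echoes'")


def read_stack(path) -> MultiEchoStack:
    """Read a stack written in either dialect (4-D file or per-echo dir)."""
    path = Path(path)
    if path.is_dir():
        te = pd.read_csv(path / "echo_times.tsv", sep="\t")["te_ms"].to_numpy()
        vols = []
        geometry = None
        for e in range(len(te)):
            vol, geometry = read_volume(path / f"echo_{e:03d}.nii.gz")
            vols.append(vol)
        return MultiEchoStack(
            data=np.stack(vols), echo_times=te, geometry=geometry
        )
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI with echo as the 4th axis")
    sidecar = path.parent / (path.name.split(".")[0] + "_echoes.json")
    te = np.asarray(json.loads(sidecar.read_text())["echo_times_ms"])
    return MultiEchoStack(
        data=np.moveaxis(data, -1, 0),
        echo_times=te,
        geometry=_geometry_from_affine(img.affine),
    )


_T2MAP_FILES = {
    "t2": "t2.nii.gz",
    "s0": "s0.nii.gz",
    "rss": "rss.nii.gz",
    "converged": "converged.nii.gz",
    "fit_mask": "fit_mask.nii.gz",
}


def write_t2map(t2map: T2Map, out_dir, geometry: VoxelGeometry | None = None) -> None:
    """Write the T2 map volumes (t2/s0/rss/converged/fit_mask) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _T2MAP_FILES.items():
        write_volume(getattr(t2map, attr), out_dir / fname, geometry)


def read_t2map(in_dir) -> tuple[T2Map, VoxelGeometry]:
    in_dir = Path(in_dir)
    vols = {}
    geometry = None
    for attr, fname in _T2MAP_FILES.items():
        vols[attr], geometry = read_volume(in_dir / fname)
    return (
        T2Map(
            t2=vols["t2"],
            s0=vols["s0"],
            rss=vols["rss"],
            converged=vols["converged"].astype(bool),
            fit_mask=vols["fit_mask"].astype(bool),
        ),
        geometry,
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
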