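"""Shared in-memory containers for the T2-mapping pipeline.

Volumes are stored as numpy arrays with axes ``(x, y, z)`` where ``z`` indexes
slices along the vessel; multi-echo data carry a leading echo axis,
``(echo, x, y, z)``.  Physical geometry (in-plane voxel size, slice thickness)
travels with the data so that areas and volumes are always computed in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGeometry", "MultiEchoStack"]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel dimensions of an image grid.

    Parameters
    ----------
    in_plane : float
        In-plane voxel edge length in mm (isotropic in-plane).
    slice_thickness : float
        Through-plane slice thickness in mm.
    """

    in_plane: float = 0.33
    slice_thickness: float = 2.0

    def __post_init__(self) -> None:
        if self.in_plane <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_area_mm2(self) -> float:
        return self.in_plane**2

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane**2 * self.slice_thickness

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (axis-aligned, origin at voxel (0,0,0))."""
        return np.diag([self.in_plane, self.in_plane, self.slice_thickness, 1.0])


@dataclass
class MultiEchoStack:
    """A multi-echo spin-echo image series: one 3-D magnitude volume per echo.

    Attributes
    ----------
    data : ndarray, shape (n_echoes, nx, ny, nz)
        Magnitude images, echo-major.
    echo_times : ndarray, shape (n_echoes,)
        Echo times in ms, strictly increasing.
    geometry : VoxelGeometry
        Physical voxel dimensions.
    """

    data: np.ndarray
    echo_times: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4-D (echo, x, y, z)")
        if self.echo_times.ndim != 1 or len(self.echo_times) != self.data.shape[0]:
            raise ValueError("echo_times must match the leading data axis")
        if len(self.echo_times) and np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if np.any(self.echo_times <= 0):
            raise ValueError("echo_times must be positive")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def n_slices(self) -> int:
        return self.data.shape[3]

    def same_grid(self, volume: np.ndarray) -> bool:
        return tuple(np.shape(volume)) == self.shape
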