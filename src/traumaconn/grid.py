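"""Voxel-grid geometry shared across the pipeline.

Conventions (recorded in every phantom manifest):
  * voxel indices are 0-based;
  * voxel (i, j, k) occupies the half-open world box
    ``[i*vs, (i+1)*vs) x [j*vs, (j+1)*vs) x [k*vs, (k+1)*vs)`` in mm;
  * the voxel *center* sits at ``(i + 0.5) * vs``;
  * the NIfTI affine therefore carries a half-voxel translation so that
    index -> world maps to voxel centers, as NIfTI requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """A regular axis-aligned voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis.
    voxel_size : tuple of float
        Edge length of a voxel along each axis, in mm.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        """Index -> world-mm affine (voxel-center convention)."""
        a = np.diag(list(self.voxel_size) + [1.0])
        a[:3, 3] = 0.5 * np.asarray(self.voxel_size)
        return a

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to integer voxel indices (may be out of bounds)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor(pts / np.asarray(self.voxel_size)).astype(np.int64)

    def voxel_centers(self, idx: np.ndarray) -> np.ndarray:
        """World-mm centers of the given (n, 3) voxel indices."""
        idx = np.atleast_2d(np.asarray(idx))
        return (idx + 0.5) * np.asarray(self.voxel_size)

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx))
        shp = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shp), axis=1)

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate arrays along each axis (mm)."""
        return tuple(
            (np.arange(n) + 0.5) * v for n, v in zip(self.shape, self.voxel_size)
        )
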