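"""Element-to-voxel mapping of scattered solver output.

Finite element solvers report strain at element centroids; the network
analysis lives on the voxel grid of the diffusion image. Each voxel takes
the arithmetic mean of all sample points falling inside its half-open box;
voxels containing no sample are marked empty and treated as zero strain
downstream (no damage), a conservative choice. Fiber orientation axes from
several bundles crossing one voxel are combined by a sign-aligned mean.
"""

from __future__ import annotations

import logging

import numpy as np

from .grid import VoxelGrid

logger = logging.getLogger(__name__)


def map_samples_to_voxels(
    positions: np.ndarray,
    values: np.ndarray,
    grid: VoxelGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Average scattered samples into voxels.

    Parameters
    ----------
    positions : (n, 3) array
        World-mm sample coordinates (e.g. element centroids).
    values : (n,) or (n, k) array
        Scalar value(s) per sample — one column per simulation increment.
    grid : VoxelGrid

    Returns
    -------
    field : array of shape ``grid.shape`` or ``grid.shape + (k,)``
        Per-voxel arithmetic mean of in-voxel samples; 0 where empty.
    counts : int array of shape ``grid.shape``
        Number of samples per voxel (0 marks an empty voxel).

    Raises
    ------
    ValueError
        If no sample falls inside the grid.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(positions)):
        raise ValueError("sample positions must be finite")
    if values.shape[0] != positions.shape[0]:
        raise ValueError("values must align with positions")

    idx = grid.world_to_voxel(positions)
    inside = grid.in_bounds(idx)
    if not inside.any():
        raise ValueError("all samples fall outside the voxel grid")
    idx = idx[inside]
    vals = values[inside]

    flat = np.ravel_multi_index(tuple(idx.T), grid.shape)
    counts_flat = np.bincount(flat, minlength=grid.n_voxels)

    scalar = vals.ndim == 1
    vals2d = vals[:, None] if scalar else vals
    sums = np.zeros((grid.n_voxels, vals2d.shape[1]))
    np.add.at(sums, flat, vals2d)
    with np.errstate(invalid="ignore"):
        means = np.where(counts_flat[:, None] > 0, sums / np.maximum(counts_flat[:, None], 1), 0.0)

    counts = counts_flat.reshape(grid.shape)
    field = means.reshape(grid.shape + (vals2d.shape[1],))
    if scalar:
        field = field[..., 0]
    return field, counts


def load_samples_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read sample points from CSV with columns x, y, z, value[, value2, ...].

    Returns (positions (n, 3) mm, values (n,) or (n, k)) — one value column
    per simulation increment.
    """
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"sample CSV must have an {col!r} column")
    positions = df[["x", "y", "z"]].to_numpy(dtype=float)
    value_cols = [c for c in df.columns if c not in ("x", "y", "z")]
    if not value_cols:
        raise ValueError("sample CSV has no value columns")
    values = df[value_cols].to_numpy(dtype=float)
    return positions, values[:, 0] if values.shape[1] == 1 else values


def average_orientations(axes: np.ndarray) -> np.ndarray:
    """Mean of a set of unit *axes* (v and -v are equivalent).

    Each vector is flipped into the hemisphere of the first principal axis
    of the set (leading eigenvector of the axis scatter matrix), then the
    flipped vectors are averaged and renormalized. For an exactly antipodal
    pair the resultant vanishes; the first axis is returned with a warning.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if axes.shape[0] < 1 or axes.shape[1] != 3:
        raise ValueError("need at least one 3-vector axis")
    norms = np.linalg.norm(axes, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length axis")
    unit = axes / norms[:, None]
    if len(unit) == 1:
        return unit[0]

    scatter = unit.T @ unit
    _, vecs = np.linalg.eigh(scatter)
    principal = vecs[:, -1]
    signs = np.where(unit @ principal < 0, -1.0, 1.0)
    mean = (unit * signs[:, None]).mean(axis=0)
    n = np.linalg.norm(mean)
    if n < 1e-12:
        logger.warning("degenerate antipodal axis set; falling back to first axis")
        return unit[0]
    return mean / n
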