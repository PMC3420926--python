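"""Streamline-voxel traversal and damage partitioning.

The injury rule is all-or-nothing at the tract level: if a streamline
traverses *any* voxel whose predicted cell death exceeds the critical
threshold, the whole streamline is removed from the tractogram, degrading
the strength of the network edge it belongs to.

Traversal uses a segment supercover: every voxel whose half-open box a
segment passes through is collected, by slicing each segment at its
grid-plane crossings and attributing each sub-interval midpoint to its
containing voxel. This is the inclusive, deterministic reading of
"traverses" and is validated against a dense-sampling oracle in the tests.
"""

from __future__ import annotations

import numpy as np

from .grid import VoxelGrid
from .tractogram import Tractogram


def _segment_voxels(p0: np.ndarray, p1: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Voxels traversed by one world-mm segment, in encounter order (may be empty)."""
    vs = np.asarray(grid.voxel_size)
    d = p1 - p0
    seg_len = np.linalg.norm(d)
    if seg_len == 0.0:
        idx = grid.world_to_voxel(p0)
        return idx[grid.in_bounds(idx)]

    ts = [0.0, 1.0]
    for a in range(3):
        if d[a] == 0.0:
            continue
        lo, hi = sorted((p0[a], p1[a]))
        first = np.ceil(lo / vs[a])
        last = np.floor(hi / vs[a])
        if last >= first:
            planes = np.arange(first, last + 1) * vs[a]
            ts.extend(((planes - p0[a]) / d[a]).tolist())
    ts = np.unique(np.clip(np.asarray(ts), 0.0, 1.0))
    mids = (ts[:-1] + ts[1:]) / 2.0
    pts = p0[None, :] + mids[:, None] * d[None, :]
    idx = grid.world_to_voxel(pts)
    return idx[grid.in_bounds(idx)]


def voxels_traversed(streamline: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Ordered unique voxel indices whose boxes the polyline intersects.

    Out-of-grid portions are ignored. A degenerate (zero-length) streamline
    yields its containing voxel only.

    Returns
    -------
    (n, 3) int array in encounter order.
    """
    v = np.asarray(streamline, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or len(v) < 1:
        raise ValueError("streamline must be an (n>=1, 3) array")
    seen: dict[tuple, None] = {}
    if len(v) == 1:
        segs = [(v[0], v[0])]
    else:
        segs = zip(v[:-1], v[1:])
    for p0, p1 in segs:
        for ijk in _segment_voxels(p0, p1, grid):
            seen.setdefault(tuple(int(x) for x in ijk), None)
    if not seen:
        return np.empty((0, 3), dtype=np.int64)
    return np.array(list(seen.keys()), dtype=np.int64)


def segment_tangent_voxels(
    streamline: np.ndarray, grid: VoxelGrid
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-segment (unit tangent, traversed voxel indices) pairs.

    Used by the phantom generator to accumulate per-voxel fiber axes from
    the streamlines that cross each voxel.
    """
    v = np.asarray(streamline, dtype=float)
    out = []
    for p0, p1 in zip(v[:-1], v[1:]):
        d = p1 - p0
        n = np.linalg.norm(d)
        if n == 0.0:
            continue
        out.append((d / n, _segment_voxels(p0, p1, grid)))
    return out


def filter_tracts_to_rois(
    tractogram: Tractogram, parcellation: np.ndarray, grid: VoxelGrid
) -> Tractogram:
    """Keep only streamlines that begin and end inside an ROI (label >= 1).

    The two endpoint labels are recorded per kept streamline. Streamlines
    with an endpoint out of the grid or in background (label 0) are dropped.
    """
    parcellation = np.asarray(parcellation)
    keep, labels = [], []
    for i, s in enumerate(tractogram.streamlines):
        ends = grid.world_to_voxel(np.vstack([s[0], s[-1]]))
        if not grid.in_bounds(ends).all():
            continue
        la = int(parcellation[tuple(ends[0])])
        lb = int(parcellation[tuple(ends[1])])
        if la >= 1 and lb >= 1:
            keep.append(i)
            labels.append((la, lb))
    return Tractogram(
        [tractogram.streamlines[i] for i in keep],
        np.asarray(labels, dtype=np.int64).reshape(len(keep), 2),
    )


def traversal_table(tractogram: Tractogram, grid: VoxelGrid) -> list[np.ndarray]:
    """Flat voxel indices traversed by each streamline (computed once, reused
    across timepoints since the tractogram geometry never changes)."""
    table = []
    for s in tractogram.streamlines:
        idx = voxels_traversed(s, grid)
        table.append(np.ravel_multi_index(tuple(idx.T), grid.shape) if len(idx) else
                     np.empty(0, dtype=np.int64))
    return table


def damaged_tracts(
    tractogram: Tractogram,
    mask: np.ndarray,
    grid: VoxelGrid,
    traversal: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition streamline ids into (intact, damaged) against a voxel mask.

    A streamline is damaged iff it traverses at least one masked voxel.
    The partition is exhaustive and disjoint.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    flat = mask.ravel()
    if traversal is None:
        traversal = traversal_table(tractogram, grid)
    damaged = np.array(
        [i for i, vox in enumerate(traversal) if len(vox) and flat[vox].any()],
        dtype=np.int64,
    )
    intact = np.setdiff1d(np.arange(len(tractogram)), damaged)
    return intact, damaged
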