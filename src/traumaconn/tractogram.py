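"""Streamline container and TRK/TCK round-trip.

A streamline is an ordered polyline of world-mm vertices approximating the
course of an axonal fiber bundle. The tractogram is the substrate that the
injury model damages: a streamline traversing any damaged voxel is removed
in its entirety, which in turn degrades the network edge it contributes to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram as _NibTractogram
from nibabel.streamlines.trk import TrkFile
from nibabel.streamlines.tck import TckFile

from .grid import VoxelGrid


def streamline_length(vertices: np.ndarray) -> float:
    """Arc length of a polyline: sum of segment Euclidean norms (mm)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError(f"streamline must be (n, 3), got {v.shape}")
    if len(v) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))


@dataclass
class Tractogram:
    """A set of streamlines with optional endpoint ROI labels.

    Attributes
    ----------
    streamlines : list of (n_i, 3) float arrays
        Vertex coordinates in world mm; each polyline has >= 2 vertices.
    endpoint_labels : (m, 2) int array or None
        ROI labels of the first and last vertex of each streamline,
        populated by ROI filtering (0 = background).
    """

    streamlines: list[np.ndarray] = field(default_factory=list)
    endpoint_labels: np.ndarray | None = None

    def __post_init__(self):
        self.streamlines = [np.asarray(s, dtype=np.float64) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValueError("each streamline must be an (n>=2, 3) array")
        if self.endpoint_labels is not None:
            self.endpoint_labels = np.asarray(self.endpoint_labels, dtype=np.int64)
            if self.endpoint_labels.shape != (len(self.streamlines), 2):
                raise ValueError("endpoint_labels must be (n_streamlines, 2)")

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def lengths(self) -> np.ndarray:
        """Per-streamline arc length in mm."""
        return np.array([streamline_length(s) for s in self.streamlines])

    def subset(self, ids) -> "Tractogram":
        ids = np.asarray(ids, dtype=np.int64)
        labels = self.endpoint_labels[ids] if self.endpoint_labels is not None else None
        return Tractogram([self.streamlines[i] for i in ids], labels)

    # ------------------------------------------------------------------ I/O

    def save(self, path: str, grid: VoxelGrid | None = None) -> None:
        """Write TRK or TCK (by extension) with a RAS+ mm affine."""
        affine = grid.affine if grid is not None else np.eye(4)
        tg = _NibTractogram(self.streamlines, affine_to_rasmm=np.eye(4))
        path = str(path)
        if path.endswith(".trk"):
            header = {
                "voxel_to_rasmm": affine.astype(np.float32),
                "voxel_sizes": np.asarray(
                    grid.voxel_size if grid else (1.0, 1.0, 1.0), dtype=np.float32
                ),
                "dimensions": np.asarray(grid.shape if grid else (1, 1, 1), dtype=np.int16),
            }
            TrkFile(tg, header).save(path)
        elif path.endswith(".tck"):
            TckFile(tg).save(path)
        else:
            raise ValueError(f"unsupported tractogram format: {path}")

    @classmethod
    def load(cls, path: str) -> "Tractogram":
        obj = nib.streamlines.load(str(path))
        return cls([np.asarray(s, dtype=np.float64) for s in obj.streamlines])
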