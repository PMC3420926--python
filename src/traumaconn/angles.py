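"""Damage as a function of fiber angle to the impact direction.

Each white-matter voxel stores one fiber-bundle axis (the averaged tangent
of the streamlines crossing it). The angle between that axis and the impact
direction lies in [0, 90] degrees — an axis is orientation-free, so a fiber
antiparallel to the impact is at 0 degrees. Damaged voxels are binned by
this angle, and the raw counts are normalized by the initial distribution
of all orientation-bearing voxels: a sparsely populated angle bin can carry
the highest *fraction* of damage even when its raw count is small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_DEG = 10.0


def fiber_impact_angle(axis: np.ndarray, impact_direction: np.ndarray) -> float | np.ndarray:
    """Angle in degrees, in [0, 90], between fiber axis and impact direction.

    Accepts a single 3-vector or an (n, 3) stack of axes. Zero vectors are
    rejected.
    """
    axis = np.asarray(axis, dtype=float)
    imp = np.asarray(impact_direction, dtype=float)
    single = axis.ndim == 1
    axes = np.atleast_2d(axis)
    an = np.linalg.norm(axes, axis=1)
    bn = np.linalg.norm(imp)
    if bn == 0 or np.any(an == 0):
        raise ValueError("zero vector has no direction")
    cosang = np.abs(axes @ imp) / (an * bn)
    deg = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(deg[0]) if single else deg


@dataclass
class AngleHistogram:
    """Damaged-voxel counts per fiber-angle bin over [0, 90] degrees.

    ``fraction`` is damaged/total per bin, NaN where the denominator is
    empty (undefined, deliberately not zero).
    """

    bin_edges: np.ndarray  # degrees, len = n_bins + 1, partitions [0, 90]
    damaged: np.ndarray  # raw damaged-voxel count per bin
    total: np.ndarray  # all orientation-bearing voxels per bin
    t_post: float = 0.0  # days

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.damaged = np.asarray(self.damaged, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if not (np.isclose(self.bin_edges[0], 0.0) and np.isclose(self.bin_edges[-1], 90.0)):
            raise ValueError("bins must partition [0, 90] degrees")
        if np.any(self.damaged > self.total):
            raise ValueError("damaged count cannot exceed total per bin")

    @property
    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.damaged / self.total.astype(float)
        return np.where(self.total > 0, f, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_deg": self.bin_edges[:-1],
            "bin_hi_deg": self.bin_edges[1:],
            "damaged": self.damaged,
            "total": self.total,
            "fraction": self.fraction,
            "t_post_days": self.t_post,
        })


def damaged_angle_histogram(
    mask: np.ndarray,
    orientation_field: np.ndarray,
    impact_direction: np.ndarray,
    bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG,
    t_post: float = 0.0,
) -> AngleHistogram:
    """Bin damaged voxels (and all orientation-bearing voxels) by fiber angle.

    Voxels without a stored orientation (NaN axis) carry no angle; masked
    voxels among them are excluded with a logged count.
    """
    mask = np.asarray(mask, dtype=bool)
    orient = np.asarray(orientation_field, dtype=float)
    if orient.shape != mask.shape + (3,):
        raise ValueError("orientation field must be mask.shape + (3,)")
    has_orient = np.all(np.isfinite(orient), axis=-1)
    dropped = int((mask & ~has_orient).sum())
    if dropped:
        logger.info("%d damaged voxels lack a fiber orientation and are excluded", dropped)

    edges = np.arange(0.0, 90.0 + bin_width_deg / 2, bin_width_deg)
    if not np.isclose(edges[-1], 90.0):
        edges = np.append(edges, 90.0)

    angles_all = fiber_impact_angle(orient[has_orient], impact_direction)
    angles_dmg = fiber_impact_angle(orient[mask & has_orient], impact_direction) \
        if (mask & has_orient).any() else np.empty(0)
    # right-closed final bin so 90 degrees is counted
    total, _ = np.histogram(angles_all, bins=edges)
    damaged, _ = np.histogram(angles_dmg, bins=edges)
    return AngleHistogram(edges, damaged, total, t_post=t_post)


def angle_normalized_histogram(hist: AngleHistogram) -> pd.DataFrame:
    """Fraction of available voxels damaged per angle bin (the Fig.-style
    normalization by the initial fiber-angle distribution); bins with an
    empty denominator are reported as NaN."""
    return hist.to_frame()
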