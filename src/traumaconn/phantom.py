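"""Digital head phantom: parcellation, fiber bundles, and strain histories.

The analysis needs three inputs that normally come from subject imaging and
an explicit-dynamic head-impact simulation: an ROI parcellation, a
tractogram whose streamlines begin and end inside ROIs, and per-voxel time
series of axonal strain and strain rate over the impact window. This module
generates all three with the statistical structure the pipeline assumes:

* an ellipsoidal brain mask parcellated into ``n_rois`` contiguous regions
  (a cortical shell plus subcortical blocks, two of which are tagged as
  hippocampus so the rate-independent death relation has a substrate);
* smooth streamline bundles between ROI pairs with heterogeneous fiber
  counts (real connectomes contain fragile edges carried by a handful of
  fibers), whose local tangents define the per-voxel fiber axis;
* a strain field that grows over a ~15 ms window with an anteroposterior
  gradient along the impact direction and a centrally peaked shear-focusing
  envelope, mimicking the coup-contrecoup pattern of a frontal impact;
  strain rate is the finite difference of strain in 1/s plus seeded noise.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .field_mapping import average_orientations
from .grid import VoxelGrid
from .tract_damage import segment_tangent_voxels
from .tractogram import Tractogram

logger = logging.getLogger(__name__)

#: fraction of ROIs placed in the subcortical core (Desikan-Killiany-like:
#: 68 cortical + 15 subcortical regions out of 83)
_SUBCORTICAL_FRACTION = 0.18
#: normalized ellipsoidal radius separating core from cortical shell
_SHELL_RHO = 0.72


@dataclass
class Phantom:
    """Self-contained stand-in for subject MRI + impact-simulation output."""

    grid: VoxelGrid
    parcellation: np.ndarray  # int labels, 0 = background
    orientation: np.ndarray  # (X, Y, Z, 3) unit axes, NaN where undefined
    region_kind: dict[int, str]  # ROI label -> death-relation region kind
    tractogram: Tractogram
    impact_direction: np.ndarray  # unit vector, anteroposterior surrogate
    seed: int
    brain_mask: np.ndarray = field(repr=False, default=None)

    @property
    def n_rois(self) -> int:
        return int(self.parcellation.max())

    def region_kind_volume(self) -> np.ndarray:
        """Per-voxel region kind ('cortex'/'hippocampus'), background ''. """
        kinds = np.full(self.grid.shape, "", dtype=object)
        for label, kind in self.region_kind.items():
            kinds[self.parcellation == label] = kind
        return kinds

    def manifest(self) -> dict:
        return {
            "grid_shape": list(self.grid.shape),
            "voxel_size_mm": list(self.grid.voxel_size),
            "n_rois": self.n_rois,
            "n_streamlines": len(self.tractogram),
            "impact_direction": [float(x) for x in self.impact_direction],
            "seed": int(self.seed),
            "voxel_indexing": "0-based",
            "coordinate_convention": "voxel-center; axis order x,y,z",
            "hippocampus_labels": sorted(
                k for k, v in self.region_kind.items() if v == "hippocampus"
            ),
        }


@dataclass
class StrainHistory:
    """Per-voxel time series of axonal strain and effective strain rate.

    ``times`` are increment times within the impact window (ms, strictly
    increasing); ``strain`` is dimensionless, ``strain_rate`` in 1/s; both
    are shaped ``grid.shape + (n_increments,)`` and finite everywhere.
    """

    times: np.ndarray
    strain: np.ndarray
    strain_rate: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("times must be a non-empty 1-d sequence")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("increment times must be strictly increasing")
        if self.strain.shape != self.strain_rate.shape:
            raise ValueError("strain and strain_rate must share one shape")
        if self.strain.shape[-1] != len(self.times):
            raise ValueError("last axis must match the number of increments")
        if not (np.all(np.isfinite(self.strain)) and np.all(np.isfinite(self.strain_rate))):
            raise ValueError("strain history must be finite")

    @property
    def grid_shape(self) -> tuple:
        return self.strain.shape[:-1]

    @property
    def n_increments(self) -> int:
        return len(self.times)


def _ellipsoid(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Brain mask and normalized ellipsoidal radius rho over the grid."""
    xs, ys, zs = grid.axis_coords()
    extent = np.asarray(grid.shape) * np.asarray(grid.voxel_size)
    center = extent / 2.0
    semi = 0.46 * extent
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    rho = np.sqrt(
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    )
    return rho <= 1.0, rho


def generate_phantom(
    n_rois: int = 83,
    grid_shape: tuple[int, int, int] = (40, 40, 40),
    n_streamlines: int = 3000,
    voxel_size: float | tuple[float, float, float] = 2.0,
    seed: int = 0,
) -> Phantom:
    """Generate a deterministic digital phantom.

    Parameters
    ----------
    n_rois : int
        Number of ROI labels (>= 2); 83 matches a Desikan-Killiany-derived
        parcellation extended with subcortical regions.
    grid_shape, voxel_size
        Voxel grid geometry (mm).
    n_streamlines : int
        Total fibers, distributed over ROI-pair bundles with heterogeneous
        counts.
    seed : int
        Seeds the single RNG stream of this module.

    Raises
    ------
    ValueError
        If the grid's brain mask is too small to host ``n_rois`` regions.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    if n_streamlines < 1:
        raise ValueError("need at least 1 streamline")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    grid = VoxelGrid(tuple(grid_shape), tuple(voxel_size))
    rng = np.random.default_rng(seed)

    mask, rho = _ellipsoid(grid)
    mask_idx = np.argwhere(mask)
    if len(mask_idx) < 4 * n_rois:
        raise ValueError(
            f"grid {grid.shape} hosts only {len(mask_idx)} brain voxels; "
            f"too small for {n_rois} ROIs (need >= {4 * n_rois})"
        )

    # --- parcellation: Voronoi regions around seed voxels ----------------
    n_sub = max(1, round(_SUBCORTICAL_FRACTION * n_rois))
    n_sub = min(n_sub, n_rois - 1)
    core_idx = np.argwhere(mask & (rho <= _SHELL_RHO))
    shell_idx = np.argwhere(mask & (rho > _SHELL_RHO))
    if len(core_idx) < n_sub or len(shell_idx) < n_rois - n_sub:
        core_idx = shell_idx = mask_idx  # tiny grids: sample anywhere

    sub_seeds = core_idx[rng.choice(len(core_idx), n_sub, replace=False)]
    cort_seeds = shell_idx[rng.choice(len(shell_idx), n_rois - n_sub, replace=False)]
    seeds = np.vstack([cort_seeds, sub_seeds])  # labels 1..n_rois
    tree = cKDTree(grid.voxel_centers(seeds))
    parcellation = np.zeros(grid.shape, dtype=np.int32)
    _, nearest = tree.query(grid.voxel_centers(mask_idx))
    parcellation[tuple(mask_idx.T)] = nearest + 1

    # subcortical labels occupy the tail; tag up to two as hippocampus so
    # the rate-independent death relation has a substrate
    sub_labels = list(range(n_rois - n_sub + 1, n_rois + 1))
    hippo = sub_labels[: min(2, len(sub_labels))]
    region_kind = {lab: "cortex" for lab in range(1, n_rois + 1)}
    for lab in hippo:
        region_kind[lab] = "hippocampus"

    # --- streamline bundles ----------------------------------------------
    voxels_by_label = {
        lab: np.argwhere(parcellation == lab) for lab in range(1, n_rois + 1)
    }
    extent = np.asarray(grid.shape) * np.asarray(grid.voxel_size)
    center = extent / 2.0
    vs = np.asarray(grid.voxel_size)

    streamlines: list[np.ndarray] = []
    endpoint_labels: list[tuple[int, int]] = []
    remaining = n_streamlines
    while remaining > 0:
        a, b = rng.choice(np.arange(1, n_rois + 1), size=2, replace=False)
        size = min(remaining, int(rng.geometric(0.25)))
        anchor_a = grid.voxel_centers(voxels_by_label[a][rng.integers(len(voxels_by_label[a]))])[0]
        anchor_b = grid.voxel_centers(voxels_by_label[b][rng.integers(len(voxels_by_label[b]))])[0]
        bundle_ctrl = 0.65 * (anchor_a + anchor_b) / 2.0 + 0.35 * center
        bundle_ctrl = bundle_ctrl + rng.normal(0, 1.5 * vs.mean(), 3)
        for _ in range(size):
            va = voxels_by_label[a][rng.integers(len(voxels_by_label[a]))]
            vb = voxels_by_label[b][rng.integers(len(voxels_by_label[b]))]
            p0 = grid.voxel_centers(va)[0] + rng.uniform(-0.3, 0.3, 3) * vs
            p1 = grid.voxel_centers(vb)[0] + rng.uniform(-0.3, 0.3, 3) * vs
            ctrl = bundle_ctrl + rng.normal(0, 0.4 * vs.mean(), 3)
            ctrl = np.clip(ctrl, 0.51 * vs, extent - 0.51 * vs)
            chord = np.linalg.norm(p1 - p0)
            k = int(np.clip(np.ceil(chord / (0.75 * vs.mean())), 3, 40))
            t = np.linspace(0.0, 1.0, k)[:, None]
            bez = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * ctrl + t**2 * p1
            streamlines.append(bez)
            endpoint_labels.append((int(a), int(b)))
        remaining -= size
    tractogram = Tractogram(streamlines, np.asarray(endpoint_labels, dtype=np.int64))

    # --- per-voxel fiber axes from streamline tangents --------------------
    axes_by_voxel: dict[int, list[np.ndarray]] = {}
    for s in tractogram.streamlines:
        for tangent, vox in segment_tangent_voxels(s, grid):
            for flat in np.ravel_multi_index(tuple(vox.T), grid.shape) if len(vox) else []:
                axes_by_voxel.setdefault(int(flat), []).append(tangent)
    orientation = np.full(grid.shape + (3,), np.nan)
    flat_view = orientation.reshape(-1, 3)
    for flat, axes in axes_by_voxel.items():
        flat_view[flat] = average_orientations(np.asarray(axes))

    impact = np.array([0.0, 1.0, 0.0])  # anteroposterior surrogate axis
    return Phantom(
        grid=grid,
        parcellation=parcellation,
        orientation=orientation,
        region_kind=region_kind,
        tractogram=tractogram,
        impact_direction=impact,
        seed=int(seed),
        brain_mask=mask,
    )


def generate_strain_history(
    phantom: Phantom,
    peak_strain: float = 0.33,
    peak_rate: float = 50.0,
    n_increments: int = 100,
    increment_ms: float = 0.15,
    seed: int = 0,
) -> StrainHistory:
    """Synthesize a strain/strain-rate history over the impact window.

    The spatial field combines an anteroposterior gradient along the
    phantom's impact direction with a centrally peaked shear-focusing
    envelope and a smooth random texture; strain ramps up in time so that
    the maximum voxel strain at the final increment equals ``peak_strain``
    (within 1e-6) and the peak finite-difference strain rate approaches
    ``peak_rate`` (1/s). Default: 100 increments of 0.15 ms = a 15 ms
    window, the duration over which an explicit-dynamic impact simulation
    resolves the transient response.
    """
    if not 0.0 <= peak_strain <= 1.0:
        raise ValueError("peak_strain must lie in [0, 1]")
    if n_increments < 1:
        raise ValueError("need at least one increment")
    grid = phantom.grid
    if phantom.parcellation.shape != grid.shape:
        raise ValueError("phantom parcellation/grid shape mismatch")
    rng = np.random.default_rng(seed)
    times = np.arange(1, n_increments + 1) * float(increment_ms)
    shape = grid.shape + (n_increments,)
    if peak_strain == 0.0:
        z = np.zeros(shape, dtype=np.float32)
        return StrainHistory(times, z, z.copy())

    mask, rho = _ellipsoid(grid)
    xs, ys, zs = grid.axis_coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    extent = np.asarray(grid.shape) * np.asarray(grid.voxel_size)
    proj = pts @ phantom.impact_direction
    span = proj[mask].max() - proj[mask].min()
    ap = 0.3 + 0.7 * (proj - proj[mask].min()) / max(span, 1e-12)
    focus = 0.25 + 0.75 * np.exp(-((rho / 0.5) ** 2))
    texture = gaussian_filter(rng.normal(size=grid.shape), sigma=2.0)
    texture = 1.0 + 0.3 * texture / max(np.abs(texture[mask]).max(), 1e-12)
    env = np.where(mask, ap * focus * np.clip(texture, 0.0, None), 0.0)
    env = env / env.max()

    # sin^2 ramp whose maximum slope realizes the requested peak rate
    window_ms = times[-1]
    slope_needed = peak_rate / (1000.0 * peak_strain)  # strain per ms
    ramp_ms = min(window_ms, np.pi / (2.0 * slope_needed)) if slope_needed > 0 else window_ms
    r = np.where(
        times <= ramp_ms, np.sin(np.pi * times / (2.0 * ramp_ms)) ** 2, 1.0
    )
    strain = (peak_strain * env)[..., None] * r[None, None, None, :]

    dt_s = np.diff(times, prepend=0.0) / 1000.0
    rate = np.diff(strain, axis=-1, prepend=np.zeros(grid.shape + (1,))) / dt_s
    noise = np.abs(rng.normal(0.0, 0.02 * peak_rate, size=shape))
    rate = rate + np.where(mask[..., None], noise, 0.0)
    return StrainHistory(
        times, strain.astype(np.float32), rate.astype(np.float32)
    )


def inject_lesion(
    history: StrainHistory,
    voxel_set: np.ndarray,
    strain_value: float,
    rate_value: float,
) -> StrainHistory:
    """Return a copy with the listed voxels held at the given strain/rate.

    Ground-truth lesion for exact-recovery tests: the listed voxels carry
    ``strain_value``/``rate_value`` at every increment, all other voxels are
    untouched. An empty voxel set returns an unchanged copy.
    """
    voxel_set = np.asarray(voxel_set, dtype=np.int64).reshape(-1, 3)
    shape = np.asarray(history.grid_shape)
    if len(voxel_set) and (np.any(voxel_set < 0) or np.any(voxel_set >= shape)):
        raise ValueError("lesion voxel index outside the grid")
    strain = history.strain.copy()
    rate = history.strain_rate.copy()
    if len(voxel_set):
        ix = tuple(voxel_set.T)
        strain[ix] = strain_value
        rate[ix] = rate_value
    return StrainHistory(history.times.copy(), strain, rate)
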