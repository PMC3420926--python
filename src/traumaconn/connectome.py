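"""Weighted structural network construction and edge degradation.

Nodes are ROIs (placed at region centroids); an undirected edge exists
between two *different* ROIs wherever at least one ROI-filtered streamline
connects them, carrying the fiber count and mean fiber length. Connection
strengths are resampled onto a Gaussian (mean 0.5, sd 0.1 by default) by
rank — the resampling compresses the scale without altering the rank order
of strong versus weak pathways — and each edge's cost is 1 - strength.

Damage never deletes nodes: removing the streamlines that traverse damaged
voxels lowers each edge's surviving fiber count, and the edge strength is
degraded proportionally. An edge whose fibers are all removed is *fully
damaged* (strength 0, disconnected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["roi_a", "roi_b", "fiber_count", "mean_length_mm", "strength", "cost"]


@dataclass
class Connectome:
    """ROI nodes plus weighted undirected edges at one post-impact time.

    ``nodes`` has columns [roi, x, y, z]; ``edges`` has EDGE_COLUMNS with
    roi_a < roi_b, no self-loops, and cost = 1 - strength exactly
    (strength is NaN until Gaussian resampling).
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    t_post: float = 0.0

    def __post_init__(self):
        self.edges = self.edges.reset_index(drop=True)
        e = self.edges
        if len(e):
            if (e.roi_a >= e.roi_b).any():
                raise ValueError("edges must satisfy roi_a < roi_b (no self-loops)")
            if (e.fiber_count < 0).any():
                raise ValueError("fiber counts must be non-negative")
            s = e.strength.to_numpy(dtype=float)
            c = e.cost.to_numpy(dtype=float)
            ok = np.isnan(s) & np.isnan(c)
            if not np.all(ok | (c == 1.0 - s)):
                raise ValueError("cost must equal 1 - strength")

    @property
    def node_ids(self) -> np.ndarray:
        return self.nodes.roi.to_numpy()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_strength(self) -> float:
        return float(np.nansum(self.edges.strength.to_numpy(dtype=float)))

    @property
    def fully_damaged_edges(self) -> pd.DataFrame:
        return self.edges[self.edges.strength == 0.0]

    def copy(self, t_post: float | None = None) -> "Connectome":
        return Connectome(
            self.nodes.copy(), self.edges.copy(),
            self.t_post if t_post is None else float(t_post),
        )

    def to_networkx(self) -> nx.Graph:
        """Graph over all nodes; only edges with positive strength are present
        (a fully damaged edge is disconnected, not a unit-cost link)."""
        g = nx.Graph()
        for _, r in self.nodes.iterrows():
            g.add_node(int(r.roi), x=float(r.x), y=float(r.y), z=float(r.z))
        live = self.edges[self.edges.strength.astype(float) > 0.0]
        for _, r in live.iterrows():
            g.add_edge(int(r.roi_a), int(r.roi_b),
                       strength=float(r.strength), cost=float(r.cost),
                       fiber_count=int(r.fiber_count))
        return g

    def strength_matrix(self) -> pd.DataFrame:
        ids = self.node_ids
        m = pd.DataFrame(0.0, index=ids, columns=ids)
        for _, r in self.edges.iterrows():
            s = 0.0 if np.isnan(r.strength) else float(r.strength)
            m.loc[int(r.roi_a), int(r.roi_b)] = s
            m.loc[int(r.roi_b), int(r.roi_a)] = s
        return m


def roi_centroids(parcellation: np.ndarray, grid) -> pd.DataFrame:
    """Node table: one row per ROI label with its centroid in world mm."""
    parcellation = np.asarray(parcellation)
    labels = np.unique(parcellation)
    labels = labels[labels >= 1]
    rows = []
    for lab in labels:
        centers = grid.voxel_centers(np.argwhere(parcellation == lab))
        c = centers.mean(axis=0)
        rows.append((int(lab), c[0], c[1], c[2]))
    return pd.DataFrame(rows, columns=["roi", "x", "y", "z"])


def build_connectome(tractogram, parcellation: np.ndarray, grid) -> Connectome:
    """Baseline network from an ROI-filtered tractogram.

    One edge per unordered ROI pair with >= 1 connecting streamline;
    fiber_count is the number of such streamlines and mean_fiber_length the
    mean of their arc lengths. Self-connections (both endpoints in the same
    ROI) stay in the tractogram but never become edges.
    """
    if tractogram.endpoint_labels is None:
        raise ValueError("tractogram must carry endpoint ROI labels (run ROI filtering)")
    nodes = roi_centroids(parcellation, grid)
    lengths = tractogram.lengths
    groups: dict[tuple[int, int], list[float]] = {}
    for (la, lb), ln in zip(tractogram.endpoint_labels, lengths):
        if la == lb:
            continue  # edges connect two *different* ROIs
        key = (min(la, lb), max(la, lb))
        groups.setdefault(key, []).append(float(ln))
    rows = [
        (a, b, len(v), float(np.mean(v)), np.nan, np.nan)
        for (a, b), v in sorted(groups.items())
    ]
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return Connectome(nodes, edges, t_post=0.0)


def resample_strengths_gaussian(
    conn: Connectome, mean: float = 0.5, sd: float = 0.1
) -> Connectome:
    """Assign strengths by mapping fiber-count ranks onto Normal quantiles.

    Edges sorted by fiber count receive the order statistics (plotting-
    position quantiles) of Normal(mean, sd): deterministic, exactly
    rank-preserving. Ties are broken by a stable sort on the ROI-pair id
    and each tied block is then re-assigned the mean of its quantile block,
    so tied counts get equal strengths. Values are clipped to
    (0.001, 0.999) so costs stay strictly positive.
    """
    if len(conn.edges) == 0:
        raise ValueError("cannot resample an empty edge set")
    e = conn.edges.copy()
    m = len(e)
    order = np.lexsort((e.roi_b.to_numpy(), e.roi_a.to_numpy(), e.fiber_count.to_numpy()))
    q = norm.ppf((np.arange(m) + 0.5) / m, loc=mean, scale=sd)
    strengths = np.empty(m)
    counts_sorted = e.fiber_count.to_numpy()[order]
    start = 0
    while start < m:
        stop = start
        while stop < m and counts_sorted[stop] == counts_sorted[start]:
            stop += 1
        strengths[order[start:stop]] = q[start:stop].mean()
        start = stop
    strengths = np.clip(strengths, 0.001, 0.999)
    e["strength"] = strengths
    e["cost"] = 1.0 - strengths
    return Connectome(conn.nodes.copy(), e, t_post=conn.t_post)


def surviving_counts(baseline: Connectome, tractogram, intact_ids) -> np.ndarray:
    """Per-edge count of baseline fibers that survive damage, aligned with
    ``baseline.edges`` rows."""
    intact = set(int(i) for i in np.asarray(intact_ids).ravel())
    counts: dict[tuple[int, int], int] = {}
    for i, (la, lb) in enumerate(tractogram.endpoint_labels):
        if la == lb:
            continue
        if i in intact:
            key = (min(la, lb), max(la, lb))
            counts[key] = counts.get(key, 0) + 1
    return np.array(
        [counts.get((int(a), int(b)), 0)
         for a, b in zip(baseline.edges.roi_a, baseline.edges.roi_b)],
        dtype=np.int64,
    )


def degrade_connectome(
    baseline: Connectome, surviving_fiber_counts, t_post: float = 0.0
) -> Connectome:
    """Degrade baseline strengths by the surviving-fiber fraction.

    s' = s * surviving / fiber_count per edge; cost = 1 - s'. An edge with
    zero survivors is fully damaged (strength exactly 0). Nodes are never
    removed. Raises if any surviving count exceeds its baseline count.
    """
    surv = np.asarray(surviving_fiber_counts, dtype=np.int64)
    e = baseline.edges.copy()
    if surv.shape != (len(e),):
        raise ValueError("surviving counts must align with baseline edges")
    base = e.fiber_count.to_numpy()
    if np.any(surv > base) or np.any(surv < 0):
        raise ValueError("surviving fiber count exceeds baseline (impossible state)")
    if e.strength.isna().any():
        raise ValueError("baseline must be Gaussian-resampled before degradation")
    frac = surv / base
    s = e.strength.to_numpy(dtype=float) * frac
    e["strength"] = s
    e["cost"] = 1.0 - s
    e["surviving_count"] = surv
    return Connectome(baseline.nodes.copy(), e, t_post=float(t_post))


def percent_degree_change(baseline: Connectome, damaged: Connectome) -> pd.Series:
    """Per-node percentage of baseline connections lost to full damage."""
    if not np.array_equal(baseline.node_ids, damaged.node_ids):
        raise ValueError("baseline and damaged connectomes must share nodes")
    deg = pd.Series(0, index=baseline.node_ids, dtype=float)
    lost = deg.copy()
    for _, r in baseline.edges.iterrows():
        deg[int(r.roi_a)] += 1
        deg[int(r.roi_b)] += 1
    for _, r in damaged.fully_damaged_edges.iterrows():
        lost[int(r.roi_a)] += 1
        lost[int(r.roi_b)] += 1
    isolated = deg == 0
    if isolated.any():
        logger.info("%d baseline nodes have no edges; percent change set to 0",
                    int(isolated.sum()))
    out = pd.Series(
        np.where(deg > 0, 100.0 * lost / deg.replace(0, 1), 0.0),
        index=deg.index, name="percent_degree_change",
    )
    return out
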