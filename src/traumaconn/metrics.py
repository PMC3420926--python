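"""Graph measures on baseline and damaged connectomes.

All distance-based measures run on edge *costs* (1 - strength): strong
connections are cheap to traverse. Global efficiency is reported normalized
by the efficiency of an ideal network — a complete graph on the same nodes
with every edge at the minimum cost of the *baseline* connectome, so the
normalization stays constant across post-impact timepoints. Local
efficiency is evaluated on each node's baseline neighbor set even after
damage removes edges, which keeps the damaged and undamaged networks
directly comparable. The small-world coefficient sigma compares weighted
clustering and characteristic path length against degree-preserving random
rewirings of the same network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome import Connectome

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


def cost_matrix(conn: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """(node_ids, dense cost matrix) with np.inf for absent edges, 0 diagonal.

    Fully damaged edges (strength 0) are absent. Raises on a non-positive
    cost of a live edge (the resampling clip prevents this upstream).
    """
    ids = conn.node_ids
    pos = {int(r): i for i, r in enumerate(ids)}
    n = len(ids)
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    live = conn.edges[conn.edges.strength.astype(float) > 0.0]
    costs = live.cost.to_numpy(dtype=float)
    if np.any(costs <= 0.0):
        raise ValueError("edge costs must be strictly positive")
    for (a, b), c in zip(zip(live.roi_a, live.roi_b), costs):
        i, j = pos[int(a)], pos[int(b)]
        w[i, j] = w[j, i] = c
    return ids, w


def _dijkstra_all(w: np.ndarray) -> np.ndarray:
    finite = np.where(np.isfinite(w), w, 0.0)
    np.fill_diagonal(finite, 0.0)
    d = dijkstra(csr_matrix(finite), directed=False)
    return d


def shortest_path_costs(conn: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances over edge costs (inf if unreachable)."""
    ids, w = cost_matrix(conn)
    return ids, _dijkstra_all(w)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].mean())


def global_efficiency(conn: Connectome) -> float:
    """Mean over node pairs of inverse shortest-path cost (0 if unreachable)."""
    _, d = shortest_path_costs(conn)
    return _efficiency_from_distances(d)


def ideal_min_cost(baseline: Connectome) -> float:
    """Minimum edge cost of the baseline network (defines the ideal network)."""
    live = baseline.edges[baseline.edges.strength.astype(float) > 0.0]
    if len(live) == 0:
        raise ValueError("baseline connectome has no live edges")
    return float(live.cost.min())


def normalized_global_efficiency(conn: Connectome, min_cost: float | None = None) -> float:
    """Global efficiency divided by that of an ideal network: a complete
    graph on the same nodes with every edge at ``min_cost`` (taken from the
    baseline so the normalization is constant over time)."""
    if min_cost is None:
        min_cost = ideal_min_cost(conn)
    if min_cost <= 0:
        raise ValueError("ideal network cost must be positive")
    e_glob = global_efficiency(conn)
    e_ideal = 1.0 / min_cost
    return e_glob / e_ideal


def baseline_neighborhoods(conn: Connectome) -> dict[int, np.ndarray]:
    """Neighbor ROI ids per node in the (undamaged) baseline network."""
    g = conn.to_networkx()
    return {int(v): np.array(sorted(g.neighbors(v)), dtype=np.int64) for v in g.nodes}


def local_efficiency_fixed_neighborhood(
    conn: Connectome, neighborhoods: dict[int, np.ndarray] | None = None
) -> pd.Series:
    """Per-node efficiency of the subgraph induced on the *baseline* neighbor
    set, evaluated on the (possibly damaged) network.

    A node keeps its baseline neighborhood even if damage removed its edge
    to a neighbor; pairs disconnected within the induced subgraph contribute
    zero. Nodes with fewer than two baseline neighbors score 0. With
    ``neighborhoods=None`` the node's own current neighborhood is used,
    which reproduces the standard weighted local efficiency.
    """
    ids, w = cost_matrix(conn)
    pos = {int(r): i for i, r in enumerate(ids)}
    if neighborhoods is None:
        neighborhoods = baseline_neighborhoods(conn)
    vals = {}
    for v in ids:
        nbrs = neighborhoods.get(int(v), np.empty(0, dtype=np.int64))
        if len(nbrs) < 2:
            vals[int(v)] = 0.0
            continue
        sub = np.array([pos[int(u)] for u in nbrs])
        d = _dijkstra_all(w[np.ix_(sub, sub)])
        vals[int(v)] = _efficiency_from_distances(d)
    return pd.Series(vals, name="local_efficiency")


def betweenness(conn: Connectome, fractional: bool = False,
                use_costs: bool = True) -> pd.Series:
    """Number of node pairs whose shortest path passes through each node.

    Default: integer counts over unordered pairs (s, t), counting v whenever
    it lies on *any* minimal-cost path (d(s,v) + d(v,t) = d(s,t)); v != s, t.
    ``fractional=True`` switches to the Brandes variant that splits credit
    among equally short paths. ``use_costs=False`` uses hop counts.
    """
    if fractional:
        g = conn.to_networkx()
        bc = nx.betweenness_centrality(
            g, weight="cost" if use_costs else None, normalized=False
        )
        return pd.Series({int(k): float(v) for k, v in bc.items()}, name="betweenness")
    ids, w = cost_matrix(conn)
    if not use_costs:
        w = np.where(np.isfinite(w) & (w > 0), 1.0, w)
    d = _dijkstra_all(w)
    n = len(ids)
    counts = np.zeros(n, dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    finite_st = np.isfinite(d[iu])
    for vi in range(n):
        through = d[iu[0], vi] + d[vi, iu[1]] <= d[iu] + _TIE_TOL
        through &= finite_st & (iu[0] != vi) & (iu[1] != vi)
        counts[vi] = int(through.sum())
    return pd.Series(counts, index=[int(i) for i in ids], name="betweenness")


def weighted_clustering(conn: Connectome) -> tuple[pd.Series, float]:
    """Per-node weighted clustering coefficient and its mean.

    Fraction of triangles around a node, each weighted by the geometric mean
    of its three edge strengths after normalization by the maximum strength
    (Onnela convention, as implemented by networkx).
    """
    g = conn.to_networkx()
    c = nx.clustering(g, weight="strength")
    s = pd.Series({int(k): float(v) for k, v in c.items()}, name="clustering")
    return s, float(s.mean()) if len(s) else 0.0


def characteristic_path_length(conn: Connectome) -> tuple[float, bool]:
    """Mean shortest-path cost over reachable node pairs.

    Returns (L, connected); when the graph is disconnected, L is computed on
    the finite pairs only and ``connected`` is False.
    """
    _, d = shortest_path_costs(conn)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    connected = bool(finite.sum() == off.sum())
    if not finite.any():
        return float("inf"), False
    if not connected:
        # the `connected` flag carries this condition into every report
        logger.debug("graph disconnected; path length computed on reachable pairs")
    return float(d[finite].mean()), connected


def random_reference(conn: Connectome, n_swap_per_edge: int = 10, seed: int = 0) -> Connectome:
    """Degree-preserving double-edge-swap rewiring with weights carried by
    the swapped stubs; seeded and reproducible.

    Attempts ``n_swap_per_edge * |E|`` swaps, rejecting any that would
    create a self-loop or a multi-edge. If no swap ever succeeds (e.g. a
    clique), the best effort is returned with a warning.
    """
    live = conn.edges[conn.edges.strength.astype(float) > 0.0]
    if len(live) < 4:
        raise ValueError("need at least 4 edges to rewire")
    rng = np.random.default_rng(seed)
    edges = [
        (int(r.roi_a), int(r.roi_b), float(r.strength), int(r.fiber_count),
         float(r.mean_length_mm))
        for _, r in live.iterrows()
    ]
    existing = {(min(a, b), max(a, b)) for a, b, *_ in edges}
    m = len(edges)
    successes = 0
    for _ in range(n_swap_per_edge * m):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b, w1, f1, l1 = edges[i]
        x, y, w2, f2, l2 = edges[j]
        if rng.integers(0, 2):
            x, y = y, x
        # (a,b),(x,y) -> (a,x),(b,y): weight follows its surviving stub pair
        if a == x or b == y:
            continue
        new1 = (min(a, x), max(a, x))
        new2 = (min(b, y), max(b, y))
        if new1 in existing or new2 in existing:
            continue
        existing.discard((min(a, b), max(a, b)))
        existing.discard((min(x, y), max(x, y)))
        existing.update((new1, new2))
        edges[i] = (new1[0], new1[1], w1, f1, l1)
        edges[j] = (new2[0], new2[1], w2, f2, l2)
        successes += 1
    if successes == 0:
        logger.warning("no degree-preserving swap was possible; returning input copy")
    df = pd.DataFrame(
        [(a, b, f, l, w, 1.0 - w) for a, b, w, f, l in edges],
        columns=["roi_a", "roi_b", "fiber_count", "mean_length_mm", "strength", "cost"],
    ).sort_values(["roi_a", "roi_b"])
    return Connectome(conn.nodes.copy(), df, t_post=conn.t_post)


def small_world_sigma(
    conn: Connectome,
    reference: Connectome | None = None,
    n_refs: int = 10,
    n_swap_per_edge: int = 10,
    seed: int = 0,
) -> float:
    """Small-world coefficient sigma = (C / C_rand) / (L / L_rand).

    C and L are the weighted clustering mean and characteristic path length;
    the random reference is either supplied explicitly or averaged over
    ``n_refs`` seeded degree-preserving rewirings.
    """
    _, c = weighted_clustering(conn)
    length, _ = characteristic_path_length(conn)
    if reference is not None:
        _, c_rand = weighted_clustering(reference)
        l_rand, _ = characteristic_path_length(reference)
    else:
        cs, ls = [], []
        for k in range(n_refs):
            ref = random_reference(conn, n_swap_per_edge, seed=seed + k)
            _, ck = weighted_clustering(ref)
            lk, _ = characteristic_path_length(ref)
            cs.append(ck)
            ls.append(lk)
        c_rand, l_rand = float(np.mean(cs)), float(np.mean(ls))
    if c_rand == 0.0 or l_rand == 0.0 or not np.isfinite(c_rand) or not np.isfinite(l_rand):
        raise ValueError(
            f"degenerate random reference (C_rand={c_rand}, L_rand={l_rand}); "
            "sigma is undefined"
        )
    return (c / c_rand) / (length / l_rand)


@dataclass
class MetricsReport:
    """Per-timepoint summary of the damaged network."""

    t_post: float  # days
    normalized_global_efficiency: float
    global_efficiency: float
    local_efficiency: pd.Series = field(repr=False)
    mean_local_efficiency: float = 0.0
    betweenness: pd.Series = field(repr=False, default=None)
    clustering: pd.Series = field(repr=False, default=None)
    mean_clustering: float = 0.0
    characteristic_path_length: float = 0.0
    connected: bool = True
    small_world_sigma: float = float("nan")
    fully_damaged_edge_percent: float = 0.0
    removed_edge_count: int = 0

    def summary(self) -> dict:
        return {
            "t_post_days": self.t_post,
            "t_post_hours": self.t_post * 24.0,
            "normalized_global_efficiency": self.normalized_global_efficiency,
            "global_efficiency": self.global_efficiency,
            "mean_local_efficiency": self.mean_local_efficiency,
            "mean_clustering": self.mean_clustering,
            "characteristic_path_length": self.characteristic_path_length,
            "connected": self.connected,
            "small_world_sigma": self.small_world_sigma,
            "fully_damaged_edge_percent": self.fully_damaged_edge_percent,
            "removed_edge_count": self.removed_edge_count,
        }


def compute_metrics(
    conn: Connectome,
    baseline: Connectome,
    neighborhoods: dict[int, np.ndarray] | None = None,
    sigma_refs: int = 10,
    sigma_seed: int = 0,
) -> MetricsReport:
    """All report measures for one (possibly damaged) connectome.

    ``baseline`` supplies the ideal-network minimum cost, the fixed local
    neighborhoods, and the denominator for the fully-damaged-edge
    percentage.
    """
    if neighborhoods is None:
        neighborhoods = baseline_neighborhoods(baseline)
    min_cost = ideal_min_cost(baseline)
    e_glob = global_efficiency(conn)
    e_norm = e_glob * min_cost
    loc = local_efficiency_fixed_neighborhood(conn, neighborhoods)
    btw = betweenness(conn)
    clus, mean_clus = weighted_clustering(conn)
    length, connected = characteristic_path_length(conn)
    sigma = small_world_sigma(conn, n_refs=sigma_refs, seed=sigma_seed)
    n_removed = int((conn.edges.strength.astype(float) == 0.0).sum())
    pct_removed = 100.0 * n_removed / len(baseline.edges) if len(baseline.edges) else 0.0
    return MetricsReport(
        t_post=conn.t_post,
        normalized_global_efficiency=e_norm,
        global_efficiency=e_glob,
        local_efficiency=loc,
        mean_local_efficiency=float(loc.mean()),
        betweenness=btw,
        clustering=clus,
        mean_clustering=mean_clus,
        characteristic_path_length=length,
        connected=connected,
        small_world_sigma=sigma,
        fully_damaged_edge_percent=pct_removed,
        removed_edge_count=n_removed,
    )
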