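"""Independent brute-force implementations used as oracles in the tests.

Everything here works by exhaustive enumeration of simple paths or
triangles on small graphs and deliberately shares no code with the package
(no scipy/networkx graph algorithms).
"""

import math
from itertools import combinations

import numpy as np


def _adj(edge_list):
    """edge list of (a, b, cost_or_strength) -> adjacency dict a->{b: w}."""
    adj = {}
    for a, b, w in edge_list:
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w
    return adj


def enumerate_simple_paths(adj, s, t):
    """All simple paths s..t as (cost, [nodes]) via DFS enumeration."""
    out = []

    def dfs(node, visited, cost, path):
        if node == t:
            out.append((cost, list(path)))
            return
        for nb, w in adj[node].items():
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                dfs(nb, visited, cost + w, path)
                path.pop()
                visited.remove(nb)

    dfs(s, {s}, 0.0, [s])
    return out


def bf_distances(nodes, cost_edges):
    """All-pairs shortest-path costs by exhaustive path enumeration."""
    adj = _adj(cost_edges)
    d = {(u, u): 0.0 for u in nodes}
    for s, t in combinations(nodes, 2):
        if s not in adj or t not in adj:
            d[(s, t)] = d[(t, s)] = math.inf
            continue
        paths = enumerate_simple_paths(adj, s, t)
        best = min((c for c, _ in paths), default=math.inf)
        d[(s, t)] = d[(t, s)] = best
    return d


def bf_global_efficiency(nodes, cost_edges):
    d = bf_distances(nodes, cost_edges)
    vals = [
        1.0 / d[(s, t)] if 0 < d[(s, t)] < math.inf else 0.0
        for s, t in combinations(nodes, 2)
    ]
    return float(np.mean(vals)) if vals else 0.0


def bf_path_length(nodes, cost_edges):
    d = bf_distances(nodes, cost_edges)
    finite = [d[(s, t)] for s, t in combinations(nodes, 2) if math.isfinite(d[(s, t)])]
    return float(np.mean(finite)) if finite else math.inf


def bf_betweenness(nodes, cost_edges, tol=1e-12):
    """Integer counts: v is counted for pair (s, t) if it lies on *any*
    minimal-cost simple path between them."""
    adj = _adj(cost_edges)
    counts = {v: 0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if s not in adj or t not in adj:
            continue
        paths = enumerate_simple_paths(adj, s, t)
        if not paths:
            continue
        best = min(c for c, _ in paths)
        on_min = set()
        for c, p in paths:
            if c <= best + tol:
                on_min.update(p[1:-1])
        for v in on_min:
            counts[v] += 1
    return counts


def bf_clustering(nodes, strength_edges):
    """Onnela weighted clustering: triangles weighted by the geometric mean
    of strengths normalized by the maximum strength."""
    adj = _adj(strength_edges)
    wmax = max((w for _, _, w in strength_edges), default=1.0)
    out = {}
    for v in nodes:
        nbrs = sorted(adj.get(v, {}))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        acc = 0.0
        for i, j in combinations(nbrs, 2):
            if j in adj.get(i, {}):
                w = (adj[v][i] / wmax) * (adj[v][j] / wmax) * (adj[i][j] / wmax)
                acc += w ** (1.0 / 3.0)
        out[v] = 2.0 * acc / (k * (k - 1))
    return out


def bf_local_efficiency_fixed(nodes, cost_edges, neighborhoods):
    """Efficiency of the induced subgraph on each node's fixed neighbor set."""
    out = {}
    for v in nodes:
        nbrs = sorted(neighborhoods.get(v, ()))
        if len(nbrs) < 2:
            out[v] = 0.0
            continue
        keep = set(nbrs)
        sub = [(a, b, w) for a, b, w in cost_edges if a in keep and b in keep]
        out[v] = bf_global_efficiency(nbrs, sub)
    return out


def dense_sample_voxels(streamline, grid, step_fraction=1.0 / 50.0):
    """Voxels hit by densely sampled points along the polyline (oracle for
    the supercover traversal)."""
    vs = min(grid.voxel_size)
    step = vs * step_fraction
    pts = []
    v = np.asarray(streamline, dtype=float)
    for p0, p1 in zip(v[:-1], v[1:]):
        seg = np.linalg.norm(p1 - p0)
        n = max(2, int(np.ceil(seg / step)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        pts.append((1 - t) * p0 + t * p1)
    pts = np.vstack(pts) if pts else v
    idx = grid.world_to_voxel(pts)
    idx = idx[grid.in_bounds(idx)]
    return {tuple(int(x) for x in row) for row in idx}
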