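"""Graph measures against hand computations and brute-force enumeration."""

import numpy as np
import pytest

from traumaconn import (
    betweenness,
    characteristic_path_length,
    global_efficiency,
    local_efficiency_fixed_neighborhood,
    normalized_global_efficiency,
    random_reference,
    shortest_path_costs,
    small_world_sigma,
    weighted_clustering,
)
from traumaconn.metrics import baseline_neighborhoods, ideal_min_cost
from conftest import make_connectome, random_sparse_graph
import oracles


# A=1, B=2, C=3 path graph with both costs 0.5 (strength 0.5 each)
PATH_ABC = [(1, 2, 0.5), (2, 3, 0.5)]
TRIANGLE = [(1, 2, 0.5), (2, 3, 0.5), (1, 3, 0.5)]


class TestHandComputedFixtures:
    def test_path_distances(self):
        conn = make_connectome(PATH_ABC)
        ids, d = shortest_path_costs(conn)
        i = {int(r): k for k, r in enumerate(ids)}
        assert d[i[1], i[3]] == pytest.approx(1.0)
        assert d[i[1], i[2]] == pytest.approx(0.5)

    def test_path_efficiencies(self):
        conn = make_connectome(PATH_ABC)
        assert global_efficiency(conn) == pytest.approx(5.0 / 3.0)
        assert normalized_global_efficiency(conn) == pytest.approx(5.0 / 6.0)

    def test_path_characteristic_length(self):
        conn = make_connectome(PATH_ABC)
        L, connected = characteristic_path_length(conn)
        assert L == pytest.approx(2.0 / 3.0)
        assert connected

    def test_path_betweenness(self):
        b = betweenness(make_connectome(PATH_ABC))
        assert b[2] == 1 and b[1] == 0 and b[3] == 0

    def test_triangle_uniform(self):
        conn = make_connectome(TRIANGLE)
        ids, d = shortest_path_costs(conn)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(d[off], 0.5)
        L, _ = characteristic_path_length(conn)
        assert L == pytest.approx(0.5)
        # complete graph at uniform cost is its own ideal network
        assert normalized_global_efficiency(conn) == pytest.approx(1.0)
        assert not betweenness(conn).any()
        clus, mean_c = weighted_clustering(conn)
        assert np.allclose(list(clus), 1.0) and mean_c == pytest.approx(1.0)

    def test_star_center_betweenness(self):
        star = [(1, k, 0.5) for k in (2, 3, 4, 5)]
        b = betweenness(make_connectome(star))
        assert b[1] == 6  # (4*3)/2 leaf pairs route through the center

    def test_path_graph_zero_clustering(self):
        clus, mean_c = weighted_clustering(make_connectome(PATH_ABC))
        assert mean_c == 0.0

    def test_single_edge_length(self):
        L, _ = characteristic_path_length(make_connectome([(1, 2, 0.7)]))
        assert L == pytest.approx(0.3)

    def test_fully_disconnected_zero_efficiency(self):
        conn = make_connectome([(1, 2, 0.5)], nodes=[1, 2, 3, 4])
        # only one reachable pair out of six
        assert global_efficiency(conn) == pytest.approx((1 / 0.5) / 6.0)


class TestBruteForceOracles:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_metrics_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 11))
        m = int(min(n * (n - 1) // 2, rng.integers(n, 2 * n)))
        triples = random_sparse_graph(rng, n, m)
        conn = make_connectome(triples, nodes=list(range(1, n + 1)))
        nodes = list(range(1, n + 1))
        cost_edges = [(a, b, 1.0 - s) for a, b, s in triples]

        assert global_efficiency(conn) == pytest.approx(
            oracles.bf_global_efficiency(nodes, cost_edges), rel=1e-9, abs=1e-9
        )
        L, _ = characteristic_path_length(conn)
        assert L == pytest.approx(oracles.bf_path_length(nodes, cost_edges), rel=1e-9)

        b = betweenness(conn)
        bf = oracles.bf_betweenness(nodes, cost_edges)
        assert {k: int(v) for k, v in b.items()} == bf

        clus, _ = weighted_clustering(conn)
        bf_c = oracles.bf_clustering(nodes, triples)
        for v in nodes:
            assert clus[v] == pytest.approx(bf_c[v], rel=1e-9, abs=1e-9)

        nbhd = {a: set() for a in nodes}
        for a, b_, _ in triples:
            nbhd[a].add(b_)
            nbhd[b_].add(a)
        loc = local_efficiency_fixed_neighborhood(conn)
        bf_l = oracles.bf_local_efficiency_fixed(nodes, cost_edges, nbhd)
        for v in nodes:
            assert loc[v] == pytest.approx(bf_l[v], rel=1e-9, abs=1e-9)


class TestLocalEfficiencyFixedNeighborhood:
    def test_neighborhood_frozen_after_damage(self):
        # node 1's neighbors at baseline: 2, 3, 4 forming a path 2-3-4
        base = make_connectome(
            [(1, 2, 0.5), (1, 3, 0.5), (1, 4, 0.5), (2, 3, 0.5), (3, 4, 0.5)]
        )
        nbhd = baseline_neighborhoods(base)
        assert set(nbhd[1]) == {2, 3, 4}
        # remove the 1-3 edge: neighborhood stays {2,3,4}
        dmg = make_connectome([(1, 2, 0.5), (1, 4, 0.5), (2, 3, 0.5), (3, 4, 0.5)],
                              nodes=[1, 2, 3, 4])
        loc_base = local_efficiency_fixed_neighborhood(base, nbhd)
        loc_dmg = local_efficiency_fixed_neighborhood(dmg, nbhd)
        assert loc_dmg[1] == pytest.approx(loc_base[1])  # 2-3-4 subgraph intact

    def test_damage_never_increases_local_efficiency(self):
        base = make_connectome(
            [(1, 2, 0.5), (1, 3, 0.5), (2, 3, 0.5), (2, 4, 0.5), (3, 4, 0.5)]
        )
        nbhd = baseline_neighborhoods(base)
        dmg = make_connectome([(1, 2, 0.5), (1, 3, 0.5), (2, 4, 0.5), (3, 4, 0.5)],
                              nodes=[1, 2, 3, 4])
        lb = local_efficiency_fixed_neighborhood(base, nbhd)
        ld = local_efficiency_fixed_neighborhood(dmg, nbhd)
        assert (ld <= lb + 1e-12).all()

    def test_disconnected_neighborhood_scores_zero(self):
        base = make_connectome([(1, 2, 0.5), (1, 3, 0.5)])
        nbhd = baseline_neighborhoods(base)
        # neighbors 2 and 3 share no edge and lose their hub: no connection
        dmg = make_connectome([(2, 3, 0.001)], nodes=[1, 2, 3])
        dmg.edges.loc[0, "strength"] = 0.0
        dmg.edges.loc[0, "cost"] = 1.0
        assert local_efficiency_fixed_neighborhood(dmg, nbhd)[1] == 0.0

    def test_small_neighborhood_zero(self):
        base = make_connectome([(1, 2, 0.5)])
        loc = local_efficiency_fixed_neighborhood(base)
        assert loc[1] == 0.0 and loc[2] == 0.0


class TestRandomReference:
    def _conn(self, seed=0, n=12, m=24):
        rng = np.random.default_rng(seed)
        return make_connectome(random_sparse_graph(rng, n, m), nodes=list(range(1, n + 1)))

    def test_degree_sequence_preserved(self):
        conn = self._conn()
        ref = random_reference(conn, n_swap_per_edge=10, seed=1)
        def degrees(c):
            d = {int(v): 0 for v in c.node_ids}
            for _, r in c.edges.iterrows():
                d[int(r.roi_a)] += 1
                d[int(r.roi_b)] += 1
            return d
        assert degrees(ref) == degrees(conn)

    def test_total_strength_preserved(self):
        conn = self._conn(seed=3)
        ref = random_reference(conn, n_swap_per_edge=10, seed=2)
        assert ref.total_strength == pytest.approx(conn.total_strength, rel=1e-12)

    def test_seeded_reproducibility(self):
        conn = self._conn(seed=5)
        a = random_reference(conn, seed=7).edges
        b = random_reference(conn, seed=7).edges
        assert a.equals(b)

    def test_rewiring_lowers_lattice_clustering(self):
        # ring lattice (k=4): high clustering; rewiring destroys triangles
        n = 20
        edges = []
        for i in range(1, n + 1):
            for step in (1, 2):
                j = (i - 1 + step) % n + 1
                edges.append((min(i, j), max(i, j), 0.5))
        lattice = make_connectome(edges, nodes=list(range(1, n + 1)))
        _, c_lattice = weighted_clustering(lattice)
        c_refs = []
        for seed in range(20):
            _, c = weighted_clustering(random_reference(lattice, seed=seed))
            c_refs.append(c)
        assert np.mean(c_refs) < c_lattice


class TestSmallWorld:
    def test_sigma_one_against_itself(self):
        conn = make_connectome(TRIANGLE + [(1, 4, 0.4), (4, 5, 0.6), (3, 5, 0.5)])
        assert small_world_sigma(conn, reference=conn) == pytest.approx(1.0)

    def test_watts_strogatz_is_small_world(self):
        import networkx as nx

        g = nx.connected_watts_strogatz_graph(40, 6, 0.1, seed=4)
        edges = [(u + 1, v + 1, 0.5) for u, v in g.edges]
        conn = make_connectome(edges, nodes=list(range(1, 41)))
        sigma = small_world_sigma(conn, n_refs=10, seed=0)
        assert sigma > 1.0

    def test_degenerate_reference_raises(self):
        conn = make_connectome([(1, 2, 0.5), (3, 4, 0.5), (5, 6, 0.5), (7, 8, 0.5)])
        with pytest.raises(ValueError, match="sigma"):
            small_world_sigma(conn, n_refs=2, seed=0)  # no triangles anywhere


class TestDamageMonotonicity:
    def test_removing_edge_never_increases_efficiency(self):
        rng = np.random.default_rng(8)
        triples = random_sparse_graph(rng, 8, 14)
        conn = make_connectome(triples, nodes=list(range(1, 9)))
        e_full = global_efficiency(conn)
        for drop in range(len(triples)):
            sub = [t for i, t in enumerate(triples) if i != drop]
            e_sub = global_efficiency(make_connectome(sub, nodes=list(range(1, 9))))
            assert e_sub <= e_full + 1e-12

    def test_increasing_cost_never_increases_efficiency(self):
        triples = [(1, 2, 0.8), (2, 3, 0.6), (1, 3, 0.3)]
        conn = make_connectome(triples)
        weaker = make_connectome([(1, 2, 0.5), (2, 3, 0.6), (1, 3, 0.3)])
        assert global_efficiency(weaker) <= global_efficiency(conn) + 1e-12


def test_normalization_uses_baseline_min_cost():
    base = make_connectome([(1, 2, 0.9), (2, 3, 0.5)])
    assert ideal_min_cost(base) == pytest.approx(0.1)
    # degraded network normalized by the same ideal cost
    dmg = make_connectome([(1, 2, 0.45), (2, 3, 0.25)])
    e_norm = normalized_global_efficiency(dmg, min_cost=ideal_min_cost(base))
    assert e_norm == pytest.approx(global_efficiency(dmg) * 0.1)
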