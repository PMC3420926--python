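"""Network construction, Gaussian rank resampling, and edge degradation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from traumaconn import (
    Connectome,
    Tractogram,
    VoxelGrid,
    build_connectome,
    degrade_connectome,
    filter_tracts_to_rois,
    percent_degree_change,
    resample_strengths_gaussian,
    surviving_counts,
)
from conftest import make_connectome


def _tractogram(pairs, grid):
    """One straight streamline per (label_a, label_b) pair on a toy parcellation."""
    parc = np.zeros(grid.shape, dtype=np.int32)
    # four ROI blocks along x
    for lab, x in [(1, 0), (2, 3), (3, 6), (4, 9)]:
        parc[x, :, :] = lab
    anchors = {1: 0.5, 2: 3.5, 3: 6.5, 4: 9.5}
    sls = []
    for i, (a, b) in enumerate(pairs):
        y = 0.5 + (i % grid.shape[1] - 1) * 0.001  # distinct but same voxel
        sls.append(np.array([[anchors[a], y, 0.5], [anchors[b], y, 0.5]]))
    return Tractogram(sls), parc


class TestBuildConnectome:
    def test_three_fibers_one_edge(self, unit_grid):
        tg, parc = _tractogram([(1, 2)] * 3, unit_grid)
        tg = filter_tracts_to_rois(tg, parc, unit_grid)
        conn = build_connectome(tg, parc, unit_grid)
        assert len(conn.edges) == 1
        assert conn.edges.fiber_count.iloc[0] == 3
        assert conn.edges.mean_length_mm.iloc[0] == pytest.approx(3.0)

    def test_self_connections_excluded(self, unit_grid):
        tg, parc = _tractogram([(1, 1), (1, 2)], unit_grid)
        tg = filter_tracts_to_rois(tg, parc, unit_grid)
        conn = build_connectome(tg, parc, unit_grid)
        assert len(tg) == 2  # retained in the tractogram
        assert len(conn.edges) == 1  # but not as an edge

    def test_no_streamlines_empty_edges(self, unit_grid):
        _, parc = _tractogram([(1, 2)], unit_grid)
        tg = Tractogram([], np.empty((0, 2), dtype=np.int64))
        conn = build_connectome(tg, parc, unit_grid)
        assert len(conn.edges) == 0
        assert conn.n_nodes == 4  # nodes come from the parcellation

    def test_counts_match_generator_bookkeeping(self, small_phantom):
        tg = filter_tracts_to_rois(
            small_phantom.tractogram, small_phantom.parcellation, small_phantom.grid
        )
        conn = build_connectome(tg, small_phantom.parcellation, small_phantom.grid)
        expect = {}
        for la, lb in tg.endpoint_labels:
            if la != lb:
                key = (min(la, lb), max(la, lb))
                expect[key] = expect.get(key, 0) + 1
        got = {
            (int(r.roi_a), int(r.roi_b)): int(r.fiber_count)
            for _, r in conn.edges.iterrows()
        }
        assert got == expect
        assert int(conn.edges.fiber_count.sum()) == sum(expect.values())


class TestGaussianResampling:
    def _conn_with_counts(self, counts):
        rows = []
        k = 0
        nodes = set()
        for i, c in enumerate(counts):
            a, b = 2 * i + 1, 2 * i + 2
            rows.append((a, b, int(c), 10.0, np.nan, np.nan))
            nodes.update((a, b))
        edges = pd.DataFrame(rows, columns=["roi_a", "roi_b", "fiber_count",
                                            "mean_length_mm", "strength", "cost"])
        ndf = pd.DataFrame({"roi": sorted(nodes), "x": 0.0, "y": 0.0, "z": 0.0})
        return Connectome(ndf, edges)

    def test_rank_preserved(self):
        conn = resample_strengths_gaussian(self._conn_with_counts([10, 5, 1]))
        s = conn.edges.strength.to_numpy()
        assert s[0] > s[1] > s[2]

    def test_spearman_is_one_without_ties(self):
        rng = np.random.default_rng(5)
        counts = rng.permutation(np.arange(1, 101))
        conn = resample_strengths_gaussian(self._conn_with_counts(counts))
        rho, _ = spearmanr(conn.edges.fiber_count, conn.edges.strength)
        assert rho == pytest.approx(1.0)

    def test_mean_sd_at_1029_edges(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 500, size=1029)
        conn = resample_strengths_gaussian(self._conn_with_counts(counts),
                                           mean=0.5, sd=0.1)
        s = conn.edges.strength.to_numpy()
        assert abs(s.mean() - 0.5) < 0.02
        assert abs(s.std(ddof=0) - 0.1) < 0.02

    def test_ties_get_equal_strengths(self):
        conn = resample_strengths_gaussian(self._conn_with_counts([4, 4, 9, 4]))
        s = conn.edges.strength.to_numpy()
        tied = s[[0, 1, 3]]
        assert np.all(tied == tied[0])
        assert s[2] > tied[0]

    def test_strengths_clipped_positive_cost(self):
        rng = np.random.default_rng(7)
        conn = resample_strengths_gaussian(
            self._conn_with_counts(rng.permutation(2000) + 1)
        )
        s = conn.edges.strength.to_numpy()
        assert np.all((s >= 0.001) & (s <= 0.999))
        assert np.all(conn.edges.cost > 0)

    def test_deterministic_idempotent_ranking(self):
        base = self._conn_with_counts([7, 3, 11, 2])
        a = resample_strengths_gaussian(base)
        b = resample_strengths_gaussian(base)
        assert np.array_equal(a.edges.strength, b.edges.strength)


class TestDegrade:
    def _baseline(self):
        conn = make_connectome([(1, 2, 0.5), (2, 3, 0.5), (1, 3, 0.5)])
        conn.edges["fiber_count"] = [4, 2, 10]
        return conn

    def test_identity_when_all_survive(self):
        base = self._baseline()
        out = degrade_connectome(base, base.edges.fiber_count.to_numpy())
        assert np.allclose(out.edges.strength, base.edges.strength)

    def test_zero_survivors_fully_damaged(self):
        base = self._baseline()
        out = degrade_connectome(base, np.array([0, 2, 10]))
        assert out.edges.strength.iloc[0] == 0.0
        assert len(out.fully_damaged_edges) == 1

    def test_half_survivors_halves_strength(self):
        base = self._baseline()
        out = degrade_connectome(base, np.array([2, 1, 5]))
        assert np.allclose(out.edges.strength, 0.25)
        assert np.allclose(out.edges.cost, 0.75)

    def test_surviving_above_baseline_rejected(self):
        base = self._baseline()
        with pytest.raises(ValueError, match="impossible"):
            degrade_connectome(base, np.array([5, 2, 10]))

    def test_nodes_never_removed(self):
        base = self._baseline()
        out = degrade_connectome(base, np.array([0, 0, 0]))
        assert np.array_equal(out.node_ids, base.node_ids)

    def test_monotone_total_strength_under_nested_damage(self):
        base = self._baseline()
        s1 = degrade_connectome(base, np.array([4, 1, 8])).total_strength
        s2 = degrade_connectome(base, np.array([2, 1, 4])).total_strength
        assert s2 <= s1 <= base.total_strength


class TestSurvivingCounts:
    def test_counts_follow_intact_ids(self, small_phantom):
        tg = filter_tracts_to_rois(
            small_phantom.tractogram, small_phantom.parcellation, small_phantom.grid
        )
        base = build_connectome(tg, small_phantom.parcellation, small_phantom.grid)
        all_ids = np.arange(len(tg))
        full = surviving_counts(base, tg, all_ids)
        assert np.array_equal(full, base.edges.fiber_count.to_numpy())
        none = surviving_counts(base, tg, np.empty(0, dtype=int))
        assert not none.any()


class TestPercentDegreeChange:
    def test_fraction_of_lost_connections(self):
        edges = [(1, k, 0.5) for k in range(2, 12)]  # node 1 has degree 10
        base = make_connectome(edges)
        surv = np.ones(10, dtype=int)
        surv[:2] = 0  # two edges fully damaged
        dmg = degrade_connectome(base, surv)
        pct = percent_degree_change(base, dmg)
        assert pct[1] == pytest.approx(20.0)

    def test_no_damage_all_zero(self):
        base = make_connectome([(1, 2, 0.4), (2, 3, 0.6)])
        dmg = degrade_connectome(base, np.array([1, 1]))
        assert not percent_degree_change(base, dmg).any()

    def test_full_damage_is_100(self):
        base = make_connectome([(1, 2, 0.4), (1, 3, 0.6)])
        dmg = degrade_connectome(base, np.array([0, 0]))
        pct = percent_degree_change(base, dmg)
        assert pct[1] == pytest.approx(100.0)

    def test_isolated_node_zero_by_convention(self):
        base = make_connectome([(1, 2, 0.5)], nodes=[1, 2, 3])
        dmg = degrade_connectome(base, np.array([1]))
        assert percent_degree_change(base, dmg)[3] == 0.0


def test_cost_strength_consistency_enforced():
    edges = pd.DataFrame(
        [(1, 2, 1, 10.0, 0.5, 0.4)],
        columns=["roi_a", "roi_b", "fiber_count", "mean_length_mm", "strength", "cost"],
    )
    nodes = pd.DataFrame({"roi": [1, 2], "x": 0.0, "y": 0.0, "z": 0.0})
    with pytest.raises(ValueError, match="cost"):
        Connectome(nodes, edges)
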