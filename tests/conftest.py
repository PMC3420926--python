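import numpy as np
import pandas as pd
import pytest

from traumaconn import Connectome, VoxelGrid, generate_phantom, generate_strain_history


def make_connectome(edge_list, nodes=None, t_post=0.0):
    """Connectome from (roi_a, roi_b, strength) triples; cost = 1 - strength."""
    rows = []
    for a, b, s in edge_list:
        a, b = int(min(a, b)), int(max(a, b))
        rows.append((a, b, 1, 10.0, float(s), 1.0 - float(s)))
    edges = pd.DataFrame(
        rows,
        columns=["roi_a", "roi_b", "fiber_count", "mean_length_mm", "strength", "cost"],
    )
    if nodes is None:
        nodes = sorted({int(a) for a, b, _ in edge_list} | {int(b) for a, b, _ in edge_list})
    ndf = pd.DataFrame({"roi": nodes, "x": 0.0, "y": 0.0, "z": 0.0})
    return Connectome(ndf, edges, t_post=t_post)


def random_sparse_graph(rng, n_nodes, n_edges):
    """Random connected-ish weighted graph as (a, b, strength) triples."""
    pairs = [(a, b) for a in range(1, n_nodes + 1) for b in range(a + 1, n_nodes + 1)]
    take = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    return [(pairs[i][0], pairs[i][1], float(rng.uniform(0.1, 0.9))) for i in take]


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(n_rois=8, grid_shape=(16, 16, 16), n_streamlines=80, seed=11)


@pytest.fixture(scope="session")
def small_history(small_phantom):
    return generate_strain_history(small_phantom, n_increments=25, seed=12)


@pytest.fixture
def unit_grid():
    return VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))
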