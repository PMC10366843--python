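"""Shared fixtures: phantoms are generated once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

import cowlabel as cl

PIPELINE_SEED = 7


@pytest.fixture(scope="session")
def phantom_complete():
    return cl.make_cow_phantom(seed=PIPELINE_SEED, variant="complete")


@pytest.fixture(scope="session")
def phantom_looped():
    return cl.make_cow_phantom(seed=PIPELINE_SEED, variant="looped")


@pytest.fixture(scope="session")
def phantom_bridged():
    return cl.make_cow_phantom(seed=PIPELINE_SEED, variant="bridged")


@pytest.fixture(scope="session")
def phantom_missing_pcomms():
    return cl.make_cow_phantom(seed=PIPELINE_SEED, variant="missing_pcomms")


def _run(ph, method):
    return cl.run_pipeline(ph.volume, ph.seeds, list(ph.specs), method=method)


@pytest.fixture(scope="session")
def pipeline_complete(phantom_complete):
    """Dijkstra pipeline result on the complete phantom."""
    return _run(phantom_complete, "dijkstra")


@pytest.fixture(scope="session")
def pipeline_complete_all(phantom_complete):
    """All three methods on the complete phantom."""
    return {m: _run(phantom_complete, m) for m in cl.METHODS}


@pytest.fixture(scope="session")
def pipeline_looped_all(phantom_looped):
    return {m: _run(phantom_looped, m) for m in cl.METHODS}


@pytest.fixture(scope="session")
def pipeline_bridged_all(phantom_bridged):
    return {m: _run(phantom_bridged, m) for m in cl.METHODS}


def graph_from_voxels(voxels, spacing=(1.0, 1.0, 1.0)):
    """Build a SkeletonGraph from a list of voxel coordinates."""
    voxels = [tuple(int(c) for c in v) for v in voxels]
    shape = tuple(max(v[i] for v in voxels) + 2 for i in range(3))
    data = np.zeros(shape, dtype=bool)
    for v in voxels:
        data[v] = True
    mask = cl.BinaryMask(data=data, spacing=spacing)
    return cl.skeleton_to_graph(mask), mask


def mean_distance_to_centerline(path_voxels, centerline_voxels) -> float:
    """Mean over path voxels of the distance to the nearest centerline voxel."""
    p = np.asarray(path_voxels, dtype=float)
    g = np.asarray(centerline_voxels, dtype=float)
    d = np.sqrt(((p[:, None, :] - g[None, :, :]) ** 2).sum(-1)).min(axis=1)
    return float(d.mean())


def random_geometric_graph(rng: np.random.Generator, max_nodes: int = 12):
    """Connected random graph with voxel positions and admissible weights.

    Node positions are distinct integer triples; edges form a random
    spanning tree plus extras; each weight is the Euclidean distance scaled
    by a factor in [1, 2), so the straight-line heuristic never
    overestimates and A* stays admissible.
    """
    import networkx as nx

    from cowlabel.skeleton import SkeletonGraph

    n = int(rng.integers(4, max_nodes + 1))
    positions = set()
    while len(positions) < n:
        positions.add(tuple(int(c) for c in rng.integers(0, 12, size=3)))
    nodes = sorted(positions)
    g = nx.Graph()
    g.add_nodes_from(nodes)

    def dist(u, v):
        return float(np.linalg.norm(np.subtract(u, v)))

    order = list(rng.permutation(n))
    for i, j in zip(order, order[1:]):
        u, v = nodes[i], nodes[j]
        g.add_edge(u, v, weight=dist(u, v) * (1.0 + float(rng.random())))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            u, v = nodes[int(i)], nodes[int(j)]
            if not g.has_edge(u, v):
                g.add_edge(u, v, weight=dist(u, v) * (1.0 + float(rng.random())))
    return SkeletonGraph(graph=g, spacing=(1.0, 1.0, 1.0))
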