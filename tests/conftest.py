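import numpy as np
import pytest

import hhomr as hh


@pytest.fixture(scope="session")
def chain_dag():
    """a -> d1 -> d2."""
    return hh.build_dag([("a", "d1"), ("d1", "d2")])


@pytest.fixture(scope="session")
def toy_graph():
    """Two miRNAs (nodes 0,1) both linked to one disease (node 2)."""
    return hh.HeteroGraph(
        mirna_ids=["m1", "m2"],
        disease_ids=["d1"],
        edge_index=np.array([[0, 2], [1, 2]]),
        mirna_features=np.zeros((2, 2)),
        disease_features=np.zeros((1, 1)),
    )


@pytest.fixture(scope="session")
def bundle():
    """Default planted-block fixture: 40x30, 3 blocks, strong signal."""
    return hh.make_fixture()


@pytest.fixture(scope="session")
def small_bundle():
    """Smaller, faster planted fixture for CV unit tests."""
    return hh.make_fixture(
        hh.FixtureSpec(n_mirnas=16, n_diseases=12, n_blocks=2, p_in=0.7, p_out=0.05, seed=1)
    )


@pytest.fixture()
def fast_model():
    return hh.MomentGNN(n_layers=1, moment_order=2, max_epochs=80, patience=15, random_state=0)


@pytest.fixture()
def fast_walks():
    return hh.WalkConfig(walks_per_node=3, walk_length=15, epochs=2, seed=0)


def random_hetero_graph(rng, max_mirnas=10, max_diseases=10, feature_dim=3):
    """Random bipartite graph with random node features, >= 1 edge."""
    n_m = int(rng.integers(2, max_mirnas + 1))
    n_d = int(rng.integers(2, max_diseases + 1))
    values = (rng.random((n_m, n_d)) < 0.4).astype(int)
    if values.sum() == 0:
        values[rng.integers(n_m), rng.integers(n_d)] = 1
    rows, cols = np.nonzero(values)
    return hh.HeteroGraph(
        mirna_ids=[f"m{i}" for i in range(n_m)],
        disease_ids=[f"d{j}" for j in range(n_d)],
        edge_index=np.stack([rows, cols + n_m], axis=1),
        mirna_features=rng.normal(size=(n_m, feature_dim)),
        disease_features=rng.normal(size=(n_d, feature_dim)),
    )


def brute_force_neighbor_mean(graph, h):
    """Oracle: plain mean of neighbor feature rows, zero for isolated nodes."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[0] != graph.n_nodes:
        h = h.T
    out = np.zeros((graph.n_nodes, h.shape[1]))
    for v in range(graph.n_nodes):
        nbrs = graph.neighbors(v)
        if nbrs.size:
            out[v] = h[nbrs].mean(axis=0)
    return out


def brute_force_neighbor_std(graph, h):
    """Oracle: per-dimension population std of neighbor features."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    out = np.zeros((graph.n_nodes, h.shape[1]))
    for v in range(graph.n_nodes):
        nbrs = graph.neighbors(v)
        if nbrs.size:
            out[v] = h[nbrs].std(axis=0)
    return out


def brute_force_auc(labels, scores):
    """Oracle: Mann-Whitney pairwise count with 0.5 per tied pair."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    count = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                count += 1.0
            elif p == q:
                count += 0.5
    return count / (len(pos) * len(neg))


def random_dag_edges(rng, max_nodes=15):
    """Random rooted tree plus a few forward cross edges (stays acyclic)."""
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    edges = [(names[int(rng.integers(i))], names[i]) for i in range(1, n)]
    for _ in range(int(rng.integers(0, n // 2 + 1))):
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if i != j and (names[i], names[j]) not in edges:
            edges.append((names[i], names[j]))
    return names, edges
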