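import numpy as np
import pytest

from kngp.network import KnowledgeNetwork, RootSet


def make_network(node_ids, edges, node_weights=None):
    """Build a KnowledgeNetwork from an edge dict {(u, v): w}."""
    node_ids = list(node_ids)
    idx = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    lw = np.zeros((n, n))
    for (u, v), w in edges.items():
        lw[idx[u], idx[v]] = lw[idx[v], idx[u]] = w
    if node_weights is None:
        nw = np.ones(n)
    else:
        nw = np.array([node_weights[nid] for nid in node_ids], dtype=float)
    return KnowledgeNetwork(node_ids=node_ids, link_weights=lw, node_weights=nw)


def random_network(rng, n, density=1.0, isolated=()):
    """Random symmetric weighted network; selected nodes kept isolated."""
    upper = np.triu(rng.random((n, n)), k=1)
    mask = np.triu(rng.random((n, n)) < density, k=1)
    lw = upper * mask
    lw = lw + lw.T
    for i in isolated:
        lw[i, :] = lw[:, i] = 0.0
    nw = rng.random(n) + 0.05
    return KnowledgeNetwork(
        node_ids=[f"n{i}" for i in range(n)], link_weights=lw, node_weights=nw
    )


@pytest.fixture
def triangle_net():
    """Three mutually linked nodes with distinct node weights."""
    return make_network(
        "abc", {("a", "b"): 1.0, ("a", "c"): 2.0, ("b", "c"): 3.0},
        node_weights={"a": 2.0, "b": 1.0, "c": 1.0},
    )


@pytest.fixture
def toy_roots():
    return RootSet(["a"])
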