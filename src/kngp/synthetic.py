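"""Seeded generator for the four synthetic benchmark networks.

Each benchmark is a complete undirected weighted graph on 1000 nodes.
Nodes 1-100 are the root set; the nodes are partitioned into five groups
(1-50, 51-100, 101-150, 151-200, 201-1000) and every node weight and
every link weight is drawn uniformly from a range determined by the
group (for nodes) or the group pair (for links).  The four datasets
differ only in those ranges and probe how root-directed bias in the link
weights versus the node weights moves the optimal f:

* dataset 1 — node weights uninformative (all U[0,1)); links among roots
  heavy (U[0.5,1)) versus U[0,0.5) elsewhere.  Only link knowledge
  separates roots, so large f wins.
* dataset 2 — root node weights U[0.5,1) versus candidate U[0,0.5); all
  links U[0,1).  Only node knowledge separates roots, so f = 0 wins.
* dataset 3 — mild bias in both: root weights U[0.9,1) vs U[0.5,1),
  root-root links U[0.55,1) vs U[0.5,1) elsewhere.
* dataset 4 — root weights U[0.95,1) vs U[0,1); links within and between
  the root groups, and from group 1 to group 3, U[0.1,1) vs U[0,1).

Draw order is fixed (node weights by node index, then links in
lexicographic pair order, each from a single uniform stream), so a seed
pins down the network exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import KnowledgeNetwork, RootSet

__all__ = ["SyntheticSpec", "generate", "GROUP_FRACTIONS", "DATASET_IDS"]

DATASET_IDS = (1, 2, 3, 4)

#: Group sizes as fractions of the node count (exact at the canonical n=1000:
#: 50, 50, 50, 50, 800); groups 1-2 are the root set.
GROUP_FRACTIONS = (0.05, 0.05, 0.05, 0.05, 0.80)

# (low, high) per group, indexed by dataset id.
_NODE_RANGES = {
    1: [(0.0, 1.0)] * 5,
    2: [(0.5, 1.0)] * 2 + [(0.0, 0.5)] * 3,
    3: [(0.9, 1.0)] * 2 + [(0.5, 1.0)] * 3,
    4: [(0.95, 1.0)] * 2 + [(0.0, 1.0)] * 3,
}


def _link_ranges(dataset_id: int) -> np.ndarray:
    """5x5 array of (low, high) for every ordered group pair (symmetric)."""
    r = np.empty((5, 5, 2))
    if dataset_id == 1:
        r[:, :] = (0.0, 0.5)
        r[:2, :2] = (0.5, 1.0)
    elif dataset_id == 2:
        r[:, :] = (0.0, 1.0)
    elif dataset_id == 3:
        r[:, :] = (0.5, 1.0)
        r[:2, :2] = (0.55, 1.0)
    elif dataset_id == 4:
        r[:, :] = (0.0, 1.0)
        r[:2, :2] = (0.1, 1.0)
        r[0, 2] = r[2, 0] = (0.1, 1.0)
    else:
        raise ValueError(f"dataset_id must be one of {DATASET_IDS}, got {dataset_id}")
    return r


@dataclass
class SyntheticSpec:
    """Recipe for one benchmark network.

    ``n_nodes`` defaults to the canonical 1000; smaller values shrink all
    five groups proportionally (useful for quick experiments) while
    keeping the same weight ranges.
    """

    dataset_id: int
    seed: int = 0
    n_nodes: int = 1000
    group_sizes: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.dataset_id not in DATASET_IDS:
            raise ValueError(
                f"dataset_id must be one of {DATASET_IDS}, got {self.dataset_id}"
            )
        if self.n_nodes < 20 or self.n_nodes % 20:
            raise ValueError("n_nodes must be a positive multiple of 20")
        sizes = [int(round(frac * self.n_nodes)) for frac in GROUP_FRACTIONS]
        sizes[-1] = self.n_nodes - sum(sizes[:-1])
        self.group_sizes = tuple(sizes)

    @property
    def n_roots(self) -> int:
        return self.group_sizes[0] + self.group_sizes[1]

    def group_of_nodes(self) -> np.ndarray:
        """Group index (0-4) of each node, in node order."""
        return np.repeat(np.arange(5), self.group_sizes)


def generate(spec: SyntheticSpec) -> tuple[KnowledgeNetwork, RootSet]:
    """Draw one network realization from the spec's seeded uniform streams.

    Node ids are "1".."n"; the first tenth of the nodes form the root
    set.  The link matrix is dense: every unordered pair receives one
    weight from its group-pair range.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    group = spec.group_of_nodes()

    node_lo_hi = np.array(_NODE_RANGES[spec.dataset_id])[group]  # (n, 2)
    node_weights = node_lo_hi[:, 0] + rng.random(n) * (node_lo_hi[:, 1] - node_lo_hi[:, 0])

    iu, ju = np.triu_indices(n, k=1)  # lexicographic pair order
    ranges = _link_ranges(spec.dataset_id)
    lo = ranges[group[iu], group[ju], 0]
    hi = ranges[group[iu], group[ju], 1]
    w = lo + rng.random(iu.size) * (hi - lo)

    lw = np.zeros((n, n))
    lw[iu, ju] = w
    lw[ju, iu] = w

    node_ids = [str(i) for i in range(1, n + 1)]
    net = KnowledgeNetwork(node_ids=node_ids, link_weights=lw, node_weights=node_weights)
    roots = RootSet(node_ids[: spec.n_roots])
    return net, roots
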