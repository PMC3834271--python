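"""Knowledge-network container, transition probabilities, and priors.

A *knowledge network* is an undirected weighted graph in which biological
knowledge is encoded twice over: pairwise knowledge (e.g. interaction
confidence, annotation similarity) lives on the links as non-negative
link weights ``lw(u, v)``, and per-gene knowledge (e.g. annotation counts)
lives on the nodes as non-negative node weights ``w_v``.

Two quantities are derived from the network before any ranking happens:

* a column-stochastic transition matrix ``Q`` in which
  ``q(v, u) = lw(u, v) / sum_t lw(u, t)`` is the probability that a random
  walker at ``u`` steps to ``v`` — this is where link knowledge enters;
* a prior probability vector ``Pr`` over nodes — this is where node
  knowledge and root-membership knowledge enter.

Two priors are provided.  The knowledge-network prior scales the node
weight of every root-set member by a factor ``f >= 0`` and normalizes:

    Pr_v  ∝  f * w_v   if v in R,
             w_v       otherwise.

At ``f = 0`` root priors vanish and candidates compete on node weight
alone; as ``f → ∞`` the prior concentrates on the root set and node
weights of candidates stop mattering.  The PageRank-with-Priors baseline
ignores node weights entirely: ``Pr_v = 1/|R|`` on roots, 0 elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeNetwork",
    "RootSet",
    "TransitionMatrix",
    "PriorVector",
    "build_transition_matrix",
    "compute_kngp_prior",
    "compute_prp_prior",
]


class NetworkValidationError(ValueError):
    """Raised when a network, root set or weight table violates an invariant."""


@dataclass
class KnowledgeNetwork:
    """Undirected weighted graph with per-node weights.

    Parameters
    ----------
    node_ids
        Ordered unique node identifiers; fixes the row/column order of
        every derived matrix and vector.
    link_weights
        ``(n, n)`` symmetric matrix of non-negative finite link weights
        with a zero diagonal (no self-loops).  A zero entry means the
        link is absent.
    node_weights
        Length-``n`` vector of non-negative finite node weights.
    """

    node_ids: list[str]
    link_weights: np.ndarray
    node_weights: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.node_ids = [str(i) for i in self.node_ids]
        self.link_weights = np.asarray(self.link_weights, dtype=float)
        self.node_weights = np.asarray(self.node_weights, dtype=float)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise NetworkValidationError("node ids are not unique")
        if self.link_weights.shape != (n, n):
            raise NetworkValidationError(
                f"link weight matrix has shape {self.link_weights.shape}, expected {(n, n)}"
            )
        if self.node_weights.shape != (n,):
            raise NetworkValidationError(
                f"node weight vector has length {self.node_weights.shape}, expected {n}"
            )
        if not np.all(np.isfinite(self.link_weights)) or not np.all(
            np.isfinite(self.node_weights)
        ):
            raise NetworkValidationError("weights must be finite")
        neg = np.argwhere(self.link_weights < 0)
        if neg.size:
            u, v = neg[0]
            raise NetworkValidationError(
                f"negative link weight between {self.node_ids[u]!r} and {self.node_ids[v]!r}"
            )
        if np.any(self.node_weights < 0):
            bad = int(np.argmax(self.node_weights < 0))
            raise NetworkValidationError(f"negative node weight for {self.node_ids[bad]!r}")
        asym = np.argwhere(self.link_weights != self.link_weights.T)
        if asym.size:
            u, v = asym[0]
            raise NetworkValidationError(
                f"asymmetric link weights for pair ({self.node_ids[u]!r}, {self.node_ids[v]!r})"
            )
        if np.any(np.diag(self.link_weights) != 0):
            raise NetworkValidationError("self-loops are not allowed (diagonal must be zero)")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def indices_of(self, node_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.index_of(i) for i in node_ids], dtype=int)


@dataclass
class RootSet:
    """The root (seed) genes: nodes already known to carry the phenotype.

    Membership order follows first appearance in the input; duplicates are
    rejected rather than silently dropped.
    """

    members: list[str]

    def __post_init__(self) -> None:
        self.members = [str(m) for m in self.members]
        if not self.members:
            raise NetworkValidationError("root set must be non-empty")
        if len(set(self.members)) != len(self.members):
            dups = sorted({m for m in self.members if self.members.count(m) > 1})
            raise NetworkValidationError(f"duplicate root ids: {dups}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, node_id: str) -> bool:
        return node_id in set(self.members)

    def validate_against(self, net: KnowledgeNetwork) -> None:
        missing = [m for m in self.members if m not in net._index]
        if missing:
            raise NetworkValidationError(f"root ids not present in the network: {missing}")


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix ``Q``; ``q[v, u]`` is ``p(v | u)``.

    Columns of isolated nodes (no positively weighted neighbour) are all
    zero, so walk mass entering such a node leaks out of the chain.
    """

    q: np.ndarray
    node_ids: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class PriorVector:
    """Normalized prior node importance ``Pr`` (sums to one).

    ``f_value`` records the root-scaling factor used to build it; ``None``
    for the PageRank-with-Priors baseline, which has no such factor.
    """

    pr: np.ndarray
    node_ids: list[str]
    f_value: float | None = None


def build_transition_matrix(net: KnowledgeNetwork) -> TransitionMatrix:
    """Normalize each node's outgoing link weights into transition probabilities.

    ``q(v, u) = lw(u, v) / sum_{t in neighbors(u)} lw(u, t)``.  A node with
    no weighted neighbour gets an all-zero column: the walker has nowhere
    to go from it and that probability mass is deliberately not
    redistributed.
    """
    col_sums = net.link_weights.sum(axis=0)
    q = np.zeros_like(net.link_weights)
    connected = col_sums > 0
    q[:, connected] = net.link_weights[:, connected] / col_sums[connected]
    return TransitionMatrix(q=q, node_ids=list(net.node_ids))


def _root_mask(net: KnowledgeNetwork, roots: RootSet) -> np.ndarray:
    roots.validate_against(net)
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[net.indices_of(roots.members)] = True
    return mask


def compute_kngp_prior(net: KnowledgeNetwork, roots: RootSet, f: float) -> PriorVector:
    """Build the knowledge-network prior: root node weights scaled by ``f``.

    The unnormalized mass is ``f * w_v`` for root members and ``w_v`` for
    everyone else; the result is normalized to sum to one.  The prior is
    therefore invariant to a global rescaling of the node weights, and
    monotone in ``f`` for every root member.
    """
    f = float(f)
    if not (f >= 0):
        raise NetworkValidationError(f"f must be non-negative, got {f}")
    mask = _root_mask(net, roots)
    mass = net.node_weights.astype(float).copy()
    mass[mask] *= f
    total = mass.sum()
    if total <= 0:
        raise NetworkValidationError(
            "prior undefined: total scaled node-weight mass is zero "
            f"(f={f}; check node weights of non-root nodes)"
        )
    return PriorVector(pr=mass / total, node_ids=list(net.node_ids), f_value=f)


def compute_prp_prior(net: KnowledgeNetwork, roots: RootSet) -> PriorVector:
    """Uniform prior over the root set (PageRank with Priors baseline).

    ``Pr_v = 1/|R|`` for root members and 0 otherwise; node weights play
    no role.
    """
    mask = _root_mask(net, roots)
    pr = np.zeros(net.n_nodes)
    pr[mask] = 1.0 / len(roots)
    return PriorVector(pr=pr, node_ids=list(net.node_ids), f_value=None)
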