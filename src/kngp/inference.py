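"""Stationary posterior node importance and candidate ranking.

The walker model: at each step, with probability ``beta`` (the back
probability) the walker jumps back to a node drawn from the prior ``Pr``;
with probability ``1 - beta`` it follows a link out of its current node
according to the transition matrix ``Q``.  The stationary distribution of
this restarted walk is the posterior node importance ``Po``, found by
iterating

    Po ← beta * Pr + (1 - beta) * Q @ Po

to a fixed point.  For ``beta > 0`` and column-stochastic ``Q`` the map is
a contraction, so the iteration converges geometrically at rate
``1 - beta`` from any starting point; we start from the zero vector, whose
iterates are the partial sums of the Neumann series
``beta * sum_k ((1-beta) Q)^k Pr``.

The pure ``beta = 0`` walk has no restart, so the fixed-point map loses
its dependence on ``Pr`` and the zero vector is itself a (degenerate)
fixed point.  In that limit we instead start the power iteration from
``Pr``, which converges to a stationary distribution of ``Q`` on
well-behaved (connected, aperiodic) chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import PriorVector, TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PosteriorVector", "propagate", "rank_candidates"]

DEFAULT_BETA = 0.3
DEFAULT_DELTA = 1e-9
DEFAULT_MAX_ITER = 10_000


@dataclass
class PosteriorVector:
    """Stationary posterior ``Po`` plus convergence diagnostics.

    On a network without isolated nodes and with ``beta > 0`` the entries
    sum to one at convergence; isolated nodes leak walk mass, in which
    case the sum falls short of one and is intentionally not renormalized.
    """

    po: np.ndarray
    node_ids: list[str]
    iterations_used: int
    converged: bool

    def as_series(self) -> pd.Series:
        return pd.Series(self.po, index=self.node_ids, name="posterior")


def propagate(
    q: TransitionMatrix,
    pr: PriorVector,
    beta: float = DEFAULT_BETA,
    delta: float = DEFAULT_DELTA,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PosteriorVector:
    """Iterate the restarted walk to its stationary posterior.

    Parameters
    ----------
    q
        Column-stochastic transition matrix.
    pr
        Prior node-importance vector (teleport distribution).
    beta
        Back probability in ``[0, 1]``: how often the walker restarts
        from the prior instead of following a link.
    delta
        Convergence threshold on the max-norm difference between
        successive iterates.
    max_iter
        Iteration cap; hitting it returns ``converged=False`` with a
        warning rather than raising.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if q.q.shape[0] != pr.pr.shape[0]:
        raise ValueError(
            f"dimension mismatch: Q is {q.q.shape}, prior has length {pr.pr.shape[0]}"
        )
    qm = q.q
    prv = pr.pr
    if beta == 1.0:
        return PosteriorVector(
            po=prv.copy(), node_ids=list(q.node_ids), iterations_used=1, converged=True
        )
    # beta = 0 makes the zero vector a trivial fixed point; seed the power
    # iteration with the prior instead so it can find a stationary
    # distribution of Q.
    po = prv.copy() if beta == 0.0 else np.zeros_like(prv)
    for iteration in range(1, max_iter + 1):
        po_next = beta * prv + (1.0 - beta) * (qm @ po)
        if not np.all(np.isfinite(po_next)):
            raise FloatingPointError(
                f"non-finite posterior values at iteration {iteration}"
            )
        diff = np.max(np.abs(po_next - po))
        po = po_next
        if diff < delta:
            return PosteriorVector(
                po=po, node_ids=list(q.node_ids), iterations_used=iteration, converged=True
            )
    logger.warning(
        "propagation did not converge in %d iterations (last max-norm step %.3e)",
        max_iter,
        diff,
    )
    return PosteriorVector(
        po=po, node_ids=list(q.node_ids), iterations_used=max_iter, converged=False
    )


def rank_candidates(po: PosteriorVector, candidates: set[str] | list[str]) -> pd.DataFrame:
    """Rank candidate nodes by posterior, highest first.

    Ties receive the average of the ranks they span, so the rank sum over
    ``L`` candidates is always ``L (L + 1) / 2``.  Rows are ordered by
    descending posterior with node id as a deterministic tie-break.

    Returns a DataFrame with columns ``node``, ``posterior``, ``rank``.
    """
    candidates = list(dict.fromkeys(str(c) for c in candidates))
    known = set(po.node_ids)
    unknown = [c for c in candidates if c not in known]
    if unknown:
        raise KeyError(f"unknown candidate ids: {unknown}")
    lookup = {nid: i for i, nid in enumerate(po.node_ids)}
    values = np.array([po.po[lookup[c]] for c in candidates])
    ranks = rankdata(-values, method="average")
    frame = pd.DataFrame({"node": candidates, "posterior": values, "rank": ranks})
    frame = frame.sort_values(
        ["posterior", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame
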