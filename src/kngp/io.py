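"""Readers and writers for the plain-text exchange formats.

Three tab-separated formats carry networks in and rankings out:

* edge list — ``node_a<TAB>node_b<TAB>weight``, one line per undirected
  pair, header optional;
* node weights — ``node<TAB>weight``; nodes that appear in the edge list
  but not here default to weight 1.0 (logged);
* root list — one node id per line.

Self-loops are stripped with a warning, zero-weight edges are kept only
for the node inventory, and a pair listed twice with conflicting weights
is an error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .network import KnowledgeNetwork, NetworkValidationError, RootSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "read_root_list",
    "write_network",
    "write_root_list",
    "write_ranking",
    "write_auc_report",
]


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_tsv(path: str | Path, n_cols: int) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise NetworkValidationError(f"{path}: file is empty")
    has_header = not _is_float(first.rstrip("\n").split("\t")[-1])
    try:
        frame = pd.read_csv(
            path, sep="\t", header=0 if has_header else None, dtype=str, comment="#"
        )
    except pd.errors.ParserError as exc:
        raise NetworkValidationError(f"{path}: {exc}") from exc
    if frame.shape[1] != n_cols:
        raise NetworkValidationError(
            f"{path}: expected {n_cols} tab-separated columns, found {frame.shape[1]}"
        )
    frame.columns = range(n_cols)
    return frame


def read_network(
    edges_path: str | Path, node_weights_path: str | Path | None = None
) -> KnowledgeNetwork:
    """Assemble a knowledge network from an edge list and a node-weight table.

    Node order is fixed by first appearance in the edge list (then in the
    weight table, for isolated nodes listed only there).  With no weight
    table every node weight defaults to 1.0.
    """
    edges = _read_tsv(edges_path, 3)
    weights = edges[2].to_numpy()
    bad = [i for i, w in enumerate(weights) if not _is_float(w)]
    if bad:
        raise NetworkValidationError(
            f"{edges_path}: non-numeric weight on data line {bad[0] + 1}"
        )
    weights = weights.astype(float)
    if np.any(~np.isfinite(weights)) or np.any(weights < 0):
        i = int(np.argmax(~np.isfinite(weights) | (weights < 0)))
        raise NetworkValidationError(
            f"{edges_path}: invalid weight {weights[i]} on data line {i + 1} "
            f"({edges.iloc[i, 0]!r}, {edges.iloc[i, 1]!r})"
        )

    order: dict[str, int] = {}
    seen: dict[tuple[str, str], float] = {}
    n_loops = 0
    for line_no, (a, b, w) in enumerate(
        zip(edges[0], edges[1], weights), start=1
    ):
        a, b = str(a), str(b)
        for node in (a, b):
            if node not in order:
                order[node] = len(order)
        if a == b:
            n_loops += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key in seen and seen[key] != w:
            raise NetworkValidationError(
                f"{edges_path}: pair {key} listed twice with conflicting weights "
                f"{seen[key]} and {w} (second at data line {line_no})"
            )
        seen[key] = w
    if n_loops:
        logger.warning("%s: stripped %d self-loop(s)", edges_path, n_loops)

    node_weight_map: dict[str, float] = {}
    if node_weights_path is not None:
        table = _read_tsv(node_weights_path, 2)
        for line_no, (node, w) in enumerate(zip(table[0], table[1]), start=1):
            node = str(node)
            if not _is_float(w):
                raise NetworkValidationError(
                    f"{node_weights_path}: non-numeric weight on data line {line_no}"
                )
            if node in node_weight_map:
                raise NetworkValidationError(
                    f"{node_weights_path}: node {node!r} listed twice"
                )
            node_weight_map[node] = float(w)
            if node not in order:
                order[node] = len(order)

    node_ids = list(order)
    n = len(node_ids)
    lw = np.zeros((n, n))
    for (a, b), w in seen.items():
        i, j = order[a], order[b]
        lw[i, j] = lw[j, i] = w

    defaulted = [nid for nid in node_ids if nid not in node_weight_map]
    if node_weight_map and defaulted:
        logger.info(
            "%d node(s) missing from the weight table default to weight 1.0 (e.g. %s)",
            len(defaulted),
            defaulted[:5],
        )
    nw = np.array([node_weight_map.get(nid, 1.0) for nid in node_ids])
    return KnowledgeNetwork(node_ids=node_ids, link_weights=lw, node_weights=nw)


def read_root_list(path: str | Path, net: KnowledgeNetwork) -> RootSet:
    """Read one root id per line and check every id exists in the network."""
    with open(path) as fh:
        members = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    roots = RootSet(members)
    roots.validate_against(net)
    return roots


def _fmt(x: float, full_precision: bool) -> str:
    return repr(float(x)) if full_precision else f"{x:.6g}"


def write_network(
    net: KnowledgeNetwork,
    edges_path: str | Path,
    node_weights_path: str | Path,
    full_precision: bool = True,
) -> None:
    """Write the edge list (upper-triangle pairs) and node-weight table."""
    iu, ju = np.nonzero(np.triu(net.link_weights, k=1))
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for i, j in zip(iu, ju):
            fh.write(
                f"{net.node_ids[i]}\t{net.node_ids[j]}\t"
                f"{_fmt(net.link_weights[i, j], full_precision)}\n"
            )
    with open(node_weights_path, "w") as fh:
        fh.write("node\tweight\n")
        for nid, w in zip(net.node_ids, net.node_weights):
            fh.write(f"{nid}\t{_fmt(w, full_precision)}\n")


def write_root_list(roots: RootSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in roots.members:
            fh.write(f"{m}\n")


def write_ranking(ranking: pd.DataFrame, path: str | Path, full_precision: bool = False) -> None:
    """Write a ranking as ``rank<TAB>node<TAB>posterior``."""
    with open(path, "w") as fh:
        fh.write("rank\tnode\tposterior\n")
        for row in ranking.itertuples(index=False):
            fh.write(f"{row.rank:g}\t{row.node}\t{_fmt(row.posterior, full_precision)}\n")


def write_auc_report(
    results: dict[float, "object"], best_f: float, path: str | Path
) -> None:
    """Write per-f AUCs as ``f<TAB>auc<TAB>best`` with the maximizer flagged."""
    with open(path, "w") as fh:
        fh.write("f\tauc\tbest\n")
        for f in sorted(results):
            flag = "*" if f == best_f else ""
            fh.write(f"{f:g}\t{results[f].auc:.6f}\t{flag}\n")
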