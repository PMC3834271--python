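"""Run configuration and the two file-to-file pipelines.

``RunConfig`` gathers every knob of a ranking or evaluation run: input
paths, the f value or grid, the back probability, convergence controls,
the list-sampling parameters and the seed.  A flat key-value YAML file
can pre-populate it; explicit keyword arguments (e.g. from CLI flags)
override file values.

``run_rank`` and ``run_evaluate`` wrap the library end to end: read the
network, build the prior(s), propagate, and write the ranking TSV or the
per-f AUC report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from . import evaluation, inference, io
from .network import RootSet, build_transition_matrix, compute_kngp_prior

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_rank", "run_evaluate"]


@dataclass
class RunConfig:
    edges: str | None = None
    node_weights: str | None = None
    roots: str | None = None
    f: float | None = None
    f_grid: tuple[float, ...] = evaluation.DEFAULT_F_GRID
    beta: float = inference.DEFAULT_BETA
    delta: float = inference.DEFAULT_DELTA
    max_iter: int = inference.DEFAULT_MAX_ITER
    k: int = evaluation.DEFAULT_SAMPLES_PER_ROOT
    list_size: int = evaluation.DEFAULT_LIST_SIZE
    seed: int = 0
    out: str | None = None
    ranks_out: str | None = None
    full_precision: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.delta <= 0 or self.max_iter < 1 or self.k < 1 or self.list_size < 2:
            raise ValueError("delta, max_iter, k and list_size are out of range")
        self.f_grid = tuple(float(x) for x in self.f_grid)
        if not self.f_grid:
            raise ValueError("f grid must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value YAML config; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def _require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"missing required configuration: {missing}")
        for n in ("edges", "node_weights", "roots"):
            value = getattr(self, n)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{n} file not found: {value}")


def run_rank(config: RunConfig):
    """Rank all candidate (non-root) nodes and write the ranking TSV.

    Returns the ranking DataFrame; the output file is written when
    ``config.out`` is set.
    """
    config._require("edges", "roots", "f")
    net = io.read_network(config.edges, config.node_weights)
    roots = io.read_root_list(config.roots, net)
    q = build_transition_matrix(net)
    prior = compute_kngp_prior(net, roots, config.f)
    post = inference.propagate(
        q, prior, beta=config.beta, delta=config.delta, max_iter=config.max_iter
    )
    logger.info(
        "propagation %s after %d iteration(s)",
        "converged" if post.converged else "did NOT converge",
        post.iterations_used,
    )
    candidates = [n for n in net.node_ids if n not in set(roots.members)]
    ranking = inference.rank_candidates(post, candidates)
    if config.out:
        io.write_ranking(ranking, config.out, full_precision=config.full_precision)
        logger.info("wrote %d-row ranking to %s", len(ranking), config.out)
    return ranking


def run_evaluate(config: RunConfig):
    """Run the leave-one-out AUC over the f grid and write the report.

    Returns ``(best_f, {f: AucResult})``; the (f, AUC) report goes to
    ``config.out`` and the raw per-list ranks, if requested, to
    ``config.ranks_out``.
    """
    config._require("edges", "roots")
    net = io.read_network(config.edges, config.node_weights)
    roots = io.read_root_list(config.roots, net)
    best_f, results = evaluation.find_best_f(
        net,
        roots,
        F=config.f_grid,
        beta=config.beta,
        k=config.k,
        L=config.list_size,
        seed=config.seed,
        delta=config.delta,
        max_iter=config.max_iter,
    )
    if config.out:
        io.write_auc_report(results, best_f, config.out)
        logger.info("wrote AUC report to %s (best f = %g)", config.out, best_f)
    if config.ranks_out:
        with open(config.ranks_out, "w") as fh:
            fh.write("f\tlist\trank\n")
            for f in sorted(results):
                for idx, rank in enumerate(results[f].list_ranks):
                    fh.write(f"{f:g}\t{idx}\t{rank:g}\n")
    return best_f, results
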