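"""End-to-end orchestration: union graph -> alignment graph -> correction ->
pruning -> seed enumeration -> module expansion."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

from .alignment import (
    AlignmentGraph,
    build_alignment_graph,
    correct_multiortholog,
    prune,
)
from .expansion import Module, discover_modules
from .io import HomologyMap, WeightedNetwork
from .seeds import (
    DEFAULT_MAX_SUBGRAPHS,
    KSubgraph,
    enumerate_and_score,
    select_seeds,
)
from .union import UnionGraph, build_union_graph, union_stats

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_alignment"]


@dataclass
class PipelineConfig:
    prune_t: float = 0.5
    k: int = 4
    min_module_size: int = 5
    tight_factor: float = 1.0
    require_clique_seeds: bool = False
    max_subgraphs: int = DEFAULT_MAX_SUBGRAPHS
    threads: int = 1

    def validate(self) -> None:
        if not 0.0 < self.prune_t < 1.0:
            raise ValueError("prune_t must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.min_module_size <= self.k:
            raise ValueError("min_module_size must exceed the seed size k")
        if self.tight_factor < 0.0:
            raise ValueError("tight_factor must be >= 0")
        if self.max_subgraphs < 1:
            raise ValueError("max_subgraphs must be >= 1")


@dataclass
class PipelineResult:
    union_graph: UnionGraph
    alignment_graph: AlignmentGraph  # corrected + pruned
    pool: list[KSubgraph]
    seeds: list[KSubgraph]
    modules: list[Module]
    stats: dict = field(default_factory=dict)


def run_alignment(
    net1: WeightedNetwork,
    net2: WeightedNetwork,
    hom: HomologyMap,
    config: PipelineConfig | None = None,
    **overrides,
) -> PipelineResult:
    """Run the full discovery pipeline and collect per-stage statistics."""
    cfg = config or PipelineConfig()
    if overrides:
        cfg = PipelineConfig(**{**asdict(cfg), **overrides})
    cfg.validate()

    ug = build_union_graph(net1, net2, hom)
    stats = {"union": union_stats(ug)}
    logger.info("union graph: %s", stats["union"])

    ag_raw = build_alignment_graph(ug)
    stats["alignment_raw"] = {
        "n_nodes": ag_raw.graph.number_of_nodes(),
        "n_edges": ag_raw.graph.number_of_edges(),
    }
    ag = prune(correct_multiortholog(ag_raw), cfg.prune_t)
    stats["alignment_pruned"] = {
        "n_nodes": ag.graph.number_of_nodes(),
        "n_edges": ag.graph.number_of_edges(),
    }

    pool = enumerate_and_score(ag, cfg.k, cfg.max_subgraphs)
    seeds = select_seeds(pool, ag, cfg.require_clique_seeds)
    stats["seeds"] = {"n_subgraphs": len(pool), "n_seeds": len(seeds)}
    logger.info("seed stage: %s", stats["seeds"])

    modules = discover_modules(
        ag,
        seeds,
        pool,
        min_module_size=cfg.min_module_size,
        tight_factor=cfg.tight_factor,
        n_jobs=cfg.threads,
    )
    stats["modules"] = {"n_modules": len(modules)}
    return PipelineResult(
        union_graph=ug,
        alignment_graph=ag,
        pool=pool,
        seeds=seeds,
        modules=modules,
        stats=stats,
    )
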