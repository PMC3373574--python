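"""Seed expansion into modules by iterative batch addition of k-subgraphs.

Starting from a seed, every pooled k-subgraph sharing at least one node with
the current module M is a candidate. Its *frontier* (nodes outside M) is
judged by how it connects to M versus to the rest of the network N: with

    W_M = total corrected score of frontier-M edges
    W_N = total corrected score of frontier-N edges   (N = V \\ (M u g))

the candidate is accepted iff W_M > tight_factor * W_N (strictly; ties
reject). W_N = 0 with W_M > 0 is the tightly-connected degenerate case and is
always accepted. All candidates are judged against the same iteration-start
snapshot of M and every accepted subgraph is added at once; the loop stops at
the fixpoint. Growth is monotone, so termination is bounded by |V|. Emitted
modules must reach 5 nodes (seed size 4 plus at least one expansion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import AlignmentGraph
from .seeds import KSubgraph, score_subgraph
from .union import Node

logger = logging.getLogger(__name__)

__all__ = [
    "FrontierLedger",
    "Module",
    "partition_edges",
    "accept_candidate",
    "expand_module",
    "discover_modules",
]


@dataclass
class FrontierLedger:
    """Edge bookkeeping for one expansion candidate.

    Edges incident to frontier nodes are classified by the other endpoint's
    membership: within the candidate subgraph g, inside the module M, or in
    the remainder N. Within-g edges count toward neither W_M nor W_N.
    """

    frontier: frozenset
    w_m: float
    w_n: float
    edges_to_g: dict = field(default_factory=dict)  # frontier node -> [(other, score)]
    edges_to_m: dict = field(default_factory=dict)
    edges_to_n: dict = field(default_factory=dict)


def partition_edges(
    ag: AlignmentGraph, module_nodes: frozenset | set, g_nodes: frozenset | set
) -> FrontierLedger | None:
    """Classify frontier-incident edges; ``None`` signals "skip candidate"
    (the subgraph lies entirely inside the module)."""
    frontier = frozenset(g_nodes) - frozenset(module_nodes)
    if not frontier:
        return None
    graph = ag.graph
    ledger = FrontierLedger(frontier=frontier, w_m=0.0, w_n=0.0)
    for v in frontier:
        for other in graph[v]:
            score = graph[v][other]["corrected"]
            if other in g_nodes:
                ledger.edges_to_g.setdefault(v, []).append((other, score))
            elif other in module_nodes:
                ledger.edges_to_m.setdefault(v, []).append((other, score))
                ledger.w_m += score
            else:
                ledger.edges_to_n.setdefault(v, []).append((other, score))
                ledger.w_n += score
    return ledger


def accept_candidate(ledger: FrontierLedger, tight_factor: float = 1.0) -> bool:
    """Accept iff the frontier connects to the module with strictly more
    reliable links than to the rest of the network."""
    return ledger.w_m > tight_factor * ledger.w_n


@dataclass
class Module:
    """One alignment solution: composite nodes with provenance."""

    id: str
    node_set: frozenset
    seed: KSubgraph
    steps: list  # [(iteration, (accepted node-frozensets...)), ...]
    score: float
    node_score: float
    edge_score: float

    @property
    def seed_nodes(self) -> frozenset:
        return self.seed.nodes

    @property
    def n_nodes(self) -> int:
        return len(self.node_set)

    @property
    def proteins1(self) -> frozenset[str]:
        return frozenset(n[1] for n in self.node_set)

    @property
    def proteins2(self) -> frozenset[str]:
        return frozenset(n[2] for n in self.node_set)


def expand_module(
    ag: AlignmentGraph,
    seed: KSubgraph,
    pool: list[KSubgraph],
    tight_factor: float = 1.0,
) -> tuple[frozenset, list]:
    """Grow one seed to its fixpoint; returns (node set, expansion steps).

    Acceptance within an iteration is evaluated against the iteration-start
    snapshot, so the result is independent of pool order.
    """
    index: dict[Node, list[int]] = {}
    for i, sg in enumerate(pool):
        for n in sg.nodes:
            index.setdefault(n, []).append(i)

    module: set = set(seed.nodes)
    exhausted: set[int] = set()  # pool entries already inside the module
    steps: list = []
    iteration = 0
    while True:
        iteration += 1
        snapshot = frozenset(module)
        candidates = {
            i for n in snapshot for i in index.get(n, ()) if i not in exhausted
        }
        accepted: list[frozenset] = []
        for i in sorted(candidates):
            g = pool[i]
            if g.nodes <= snapshot:
                exhausted.add(i)
                continue
            ledger = partition_edges(ag, snapshot, g.nodes)
            if ledger is not None and accept_candidate(ledger, tight_factor):
                accepted.append(g.nodes)
        if not accepted:
            break
        for nodes in accepted:
            module |= nodes
        steps.append((iteration, tuple(sorted(accepted, key=sorted))))
    return frozenset(module), steps


def discover_modules(
    ag: AlignmentGraph,
    seed_list: list[KSubgraph],
    pool: list[KSubgraph],
    min_module_size: int = 5,
    tight_factor: float = 1.0,
    n_jobs: int = 1,
) -> list[Module]:
    """Expand every seed independently; drop undersized modules, deduplicate
    identical node sets (first/highest-scoring seed wins), sort by score."""
    if n_jobs != 1 and len(seed_list) > 1:
        from joblib import Parallel, delayed

        expansions = Parallel(n_jobs=n_jobs)(
            delayed(expand_module)(ag, seed, pool, tight_factor)
            for seed in seed_list
        )
    else:
        expansions = [
            expand_module(ag, seed, pool, tight_factor) for seed in seed_list
        ]

    seen: set[frozenset] = set()
    modules: list[Module] = []
    for seed, (node_set, steps) in zip(seed_list, expansions):
        if len(node_set) < min_module_size:
            continue
        if node_set in seen:
            continue
        seen.add(node_set)
        node_score = sum(ag.graph.nodes[n]["node_score"] for n in node_set)
        total = score_subgraph(node_set, ag)
        modules.append(
            Module(
                id="",
                node_set=node_set,
                seed=seed,
                steps=steps,
                score=total,
                node_score=node_score,
                edge_score=total - node_score,
            )
        )
    modules.sort(key=lambda m: (-m.score, tuple(sorted(m.node_set))))
    for i, m in enumerate(modules, 1):
        m.id = f"M{i:04d}"
    logger.info(
        "module discovery: %d seeds -> %d modules (>= %d nodes)",
        len(seed_list),
        len(modules),
        min_module_size,
    )
    return modules
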