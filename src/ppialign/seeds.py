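"""Connected k-subgraph enumeration, scoring, and seed selection.

Every connected node-induced subgraph of k nodes (k = 4 by default) is
enumerated exactly once by an anchored scheme: nodes are given an arbitrary
fixed order, and for each anchor only later-ordered nodes reachable through
the growing subgraph may extend it (the classic exact-enumeration strategy
for network motifs). Subgraphs score the sum of their node scores (homology
confidences) and induced corrected edge scores; the node-disjoint top scorers
become seeds while the full enumeration remains available as the expansion
candidate pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .alignment import AlignmentGraph
from .union import Node

logger = logging.getLogger(__name__)

__all__ = [
    "KSubgraph",
    "enumerate_connected_ksubgraphs",
    "score_subgraph",
    "enumerate_and_score",
    "select_seeds",
]

DEFAULT_MAX_SUBGRAPHS = 5_000_000


@dataclass(frozen=True)
class KSubgraph:
    """A connected node-induced k-subgraph of the alignment graph."""

    nodes: frozenset
    score: float

    def sort_key(self):
        return (-self.score, tuple(sorted(self.nodes)))


def enumerate_connected_ksubgraphs(
    ag: AlignmentGraph, k: int, max_subgraphs: int | None = DEFAULT_MAX_SUBGRAPHS
) -> Iterator[frozenset]:
    """Yield every connected k-node set exactly once.

    Enumeration is streamed; when ``max_subgraphs`` is hit the stream stops
    with a logged warning (dense graphs explode combinatorially).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    g = ag.graph
    order = {v: i for i, v in enumerate(sorted(g.nodes))}
    count = 0

    def extend(sub: tuple, ext: set, root_i: int, seen: frozenset) -> Iterator[frozenset]:
        # `seen` is sub plus its neighborhood at the time each branch forked;
        # only exclusive neighbors of the newly added node enter the extension.
        if len(sub) == k:
            yield frozenset(sub)
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_ext = ext | {
                u for u in g[w] if order[u] > root_i and u not in seen
            }
            yield from extend(
                sub + (w,), new_ext, root_i, seen | set(g[w]) | {w}
            )

    for v in sorted(g.nodes):
        root_i = order[v]
        ext = {u for u in g[v] if order[u] > root_i}
        for sub in extend((v,), ext, root_i, frozenset(g[v]) | {v}):
            yield sub
            count += 1
            if max_subgraphs is not None and count >= max_subgraphs:
                logger.warning(
                    "subgraph enumeration truncated at %d subgraphs", count
                )
                return


def score_subgraph(nodes: Iterable[Node], ag: AlignmentGraph) -> float:
    """Additive subgraph score: node confidences + induced corrected edges."""
    nodes = set(nodes)
    g = ag.graph
    missing = nodes - set(g.nodes)
    if missing:
        raise ValueError(f"unknown alignment-graph nodes: {sorted(missing)}")
    sub = g.subgraph(nodes)
    return sum(g.nodes[n]["node_score"] for n in nodes) + sum(
        d["corrected"] for _, _, d in sub.edges(data=True)
    )


def enumerate_and_score(
    ag: AlignmentGraph, k: int = 4, max_subgraphs: int | None = DEFAULT_MAX_SUBGRAPHS
) -> list[KSubgraph]:
    return [
        KSubgraph(nodes, score_subgraph(nodes, ag))
        for nodes in enumerate_connected_ksubgraphs(ag, k, max_subgraphs)
    ]


def _is_clique(nodes: frozenset, ag: AlignmentGraph) -> bool:
    n = len(nodes)
    return ag.graph.subgraph(nodes).number_of_edges() == n * (n - 1) // 2


def select_seeds(
    subgraphs: Sequence[KSubgraph],
    ag: AlignmentGraph | None = None,
    require_clique: bool = False,
) -> list[KSubgraph]:
    """Greedy sweep in descending score; a subgraph becomes a seed iff it is
    node-disjoint from every previously selected seed.

    Ties break on the lexicographically smallest node set. With
    ``require_clique`` only fully connected subgraphs are eligible (the
    stricter reading of seed quality); all enumerated subgraphs, seed or not,
    remain available to the expansion stage.
    """
    if require_clique and ag is None:
        raise ValueError("require_clique needs the alignment graph")
    taken: set = set()
    seeds: list[KSubgraph] = []
    for sg in sorted(subgraphs, key=KSubgraph.sort_key):
        if require_clique and not _is_clique(sg.nodes, ag):
            continue
        if sg.nodes & taken:
            continue
        seeds.append(sg)
        taken |= sg.nodes
    return seeds
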