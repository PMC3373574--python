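"""Merging two weighted networks and a homology map into a union graph.

The union graph keeps every input interaction while overlaying the homology
map: *composite* nodes are putative ortholog pairs (one protein per species),
*simple* nodes are proteins with no homolog in the other network. Every input
edge is replicated between all union-graph nodes containing its endpoints, so
no information is lost; an unordered node pair supported by both species
carries a single edge whose score is the sum of the two contributions.

Node encodings (plain string tuples, hence sortable and hashable):

* composite: ``("c", protein_species1, protein_species2)``
* simple:    ``("s", species_label, protein)``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx

from .io import HomologyMap, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = ["UnionGraph", "build_union_graph", "union_stats"]

Node = tuple  # ("c", p1, p2) | ("s", species, protein)


def is_composite(node: Node) -> bool:
    return node[0] == "c"


@dataclass
class UnionGraph:
    """Merged two-network structure with per-species edge support.

    Edge attributes: ``s1``/``s2`` — the reliability contributed by each
    species (0.0 when absent), ``score = s1 + s2``, ``sup`` — frozenset of
    contributing species indices, ``support`` — human-readable label.
    Composite nodes carry ``conf`` (homology confidence).
    """

    graph: nx.Graph
    species: tuple[str, str]

    @property
    def composites(self) -> set[Node]:
        return {n for n in self.graph if is_composite(n)}

    @property
    def simples(self) -> set[Node]:
        return {n for n in self.graph if not is_composite(n)}

    def composite_neighbors(self, node: Node) -> Iterator[Node]:
        return (n for n in self.graph[node] if is_composite(n))


def _support_label(sup: frozenset[int], species: tuple[str, str]) -> str:
    if sup == frozenset({1, 2}):
        return "both"
    return species[next(iter(sup)) - 1]


def build_union_graph(
    net1: WeightedNetwork, net2: WeightedNetwork, hom: HomologyMap
) -> UnionGraph:
    """Merge the two networks and the homology map without losing information.

    Composite nodes are restricted to homology pairs whose both proteins occur
    in their respective networks (absent proteins cannot contribute edges).
    A protein involved in several homology pairs appears in several composite
    nodes, so one input edge may be replicated into several union edges.
    """
    if not net1.graph or not net2.graph:
        raise ValueError("both input networks must be non-empty")
    if net1.species == net2.species:
        raise ValueError("the two networks must carry distinct species labels")

    g = nx.Graph()
    containing: tuple[dict[str, list[Node]], dict[str, list[Node]]] = ({}, {})
    for p1, p2, conf in hom:
        if p1 not in net1.graph or p2 not in net2.graph:
            continue
        node = ("c", p1, p2)
        g.add_node(node, conf=conf)
        containing[0].setdefault(p1, []).append(node)
        containing[1].setdefault(p2, []).append(node)

    # simple nodes: proteins with no (retained) homology pairing
    for idx, net in ((0, net1), (1, net2)):
        for p in net.graph.nodes:
            if p not in containing[idx]:
                node = ("s", net.species, p)
                g.add_node(node)
                containing[idx][p] = [node]

    contrib: dict[tuple[Node, Node], list[float]] = {}
    for sidx, net in ((1, net1), (2, net2)):
        holders = containing[sidx - 1]
        for u, v, w in net.edges():
            for a in holders[u]:
                for b in holders[v]:
                    key = (a, b) if a <= b else (b, a)
                    entry = contrib.setdefault(key, [0.0, 0.0])
                    entry[sidx - 1] += w

    species = (net1.species, net2.species)
    for (a, b), (s1, s2) in contrib.items():
        sup = frozenset(i for i, s in ((1, s1), (2, s2)) if s > 0.0)
        g.add_edge(
            a,
            b,
            s1=s1,
            s2=s2,
            score=s1 + s2,
            sup=sup,
            support=_support_label(sup, species),
        )
    return UnionGraph(graph=g, species=species)


def union_stats(ug: UnionGraph) -> dict:
    """Node/edge counts by class, for stage logging."""
    by_support: dict[str, int] = {}
    for _, _, d in ug.graph.edges(data=True):
        by_support[d["support"]] = by_support.get(d["support"], 0) + 1
    composites = ug.composites
    return {
        "n_nodes": ug.graph.number_of_nodes(),
        "n_composite": len(composites),
        "n_simple": ug.graph.number_of_nodes() - len(composites),
        "n_edges": ug.graph.number_of_edges(),
        "edges_by_support": by_support,
    }
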