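"""Shared test helpers: random instance generators and independent oracles.

The oracles here deliberately recompute quantities by exhaustive brute force
(all-pairs, all-subsets, direct summation) so they stay independent of the
package's neighborhood-scanning implementations.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from ppialign import (
    AlignmentGraph,
    HomologyMap,
    WeightedNetwork,
    build_union_graph,
)
from ppialign.union import UnionGraph, is_composite

# ---------------------------------------------------------------------------
# random instance generators
# ---------------------------------------------------------------------------


def random_network(
    rng: np.random.Generator, species: str, n: int, p: float
) -> WeightedNetwork:
    names = [f"{species}{i}" for i in range(n)]
    edges = [
        (names[i], names[j], float(rng.uniform(0.05, 1.0)))
        for i, j in combinations(range(n), 2)
        if rng.random() < p
    ]
    return WeightedNetwork.from_edges(species, edges, nodes=names)


def random_instance(
    rng: np.random.Generator,
    n1: int = 10,
    n2: int = 10,
    p_edge: float = 0.3,
    n_hom: int = 8,
):
    """A random pair of networks plus a random many-to-many homology map."""
    net1 = random_network(rng, "a", n1, p_edge)
    net2 = random_network(rng, "b", n2, p_edge)
    records = {}
    for _ in range(n_hom):
        i = int(rng.integers(0, n1))
        j = int(rng.integers(0, n2))
        records[(f"a{i}", f"b{j}")] = float(rng.uniform(0.1, 1.0))
    hom = HomologyMap.from_records([(p1, p2, c) for (p1, p2), c in records.items()])
    return net1, net2, hom


def random_union_graph(rng: np.random.Generator, **kw) -> UnionGraph:
    return build_union_graph(*random_instance(rng, **kw))


def random_alignment_graph(
    rng: np.random.Generator, n: int, p: float, shared_protein_prob: float = 0.0
) -> AlignmentGraph:
    """A synthetic scored alignment graph built directly (for stages that
    only consume corrected scores). Composite identities can be made to
    collide on the species-1 protein to exercise ortholog-group logic."""
    nodes = []
    for i in range(n):
        p1 = f"x{i // 2}" if rng.random() < shared_protein_prob else f"x{i}"
        nodes.append(("c", p1, f"y{i}"))
    g = nx.Graph()
    for node in nodes:
        g.add_node(node, node_score=float(rng.uniform(0.1, 1.0)))
    for a, b in combinations(nodes, 2):
        if rng.random() < p:
            s = float(rng.uniform(0.05, 2.0))
            g.add_edge(a, b, score=s, corrected=s)
    return AlignmentGraph(g, ("sp1", "sp2"))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_path_collections(ug: UnionGraph):
    """Exhaustively enumerate direct edges and valid length-2 paths between
    composite nodes, by scanning every node triple."""
    g = ug.graph
    composites = sorted(ug.composites)
    direct = {}
    for a, b in combinations(composites, 2):
        if g.has_edge(a, b):
            direct[(a, b)] = g[a][b]["score"]
    paths = {}  # (a, b) -> list of path scores
    for a, b in combinations(composites, 2):
        for x in g.nodes:
            if x in (a, b):
                continue
            if g.has_edge(a, x) and g.has_edge(x, b):
                if g[a][x]["sup"] & g[x][b]["sup"]:
                    paths.setdefault((a, b), []).append(
                        g[a][x]["score"] + g[x][b]["score"]
                    )
    return composites, direct, paths


def oracle_eli_scores(ug: UnionGraph):
    """All-pairs edge scores per the direct+indirect Jaccard-style formula,
    computed from the exhaustive path collections."""
    composites, direct, paths = oracle_path_collections(ug)
    s1 = {n: 0.0 for n in composites}
    s2 = {n: 0.0 for n in composites}
    for (a, b), w in direct.items():
        s1[a] += w
        s1[b] += w
    for (a, b), scores in paths.items():
        s2[a] += sum(scores)
        s2[b] += sum(scores)
    out = {}
    for pair in set(direct) | set(paths):
        a, b = pair
        w1 = direct.get(pair, 0.0)
        p2 = sum(paths.get(pair, []))
        c_dir = w1 / (s1[a] + s1[b] - w1) if w1 > 0 else 0.0
        c_ind = p2 / (s2[a] + s2[b] - p2) if p2 > 0 else 0.0
        if c_dir + c_ind > 0:
            out[frozenset(pair)] = c_dir + c_ind
    return out


def oracle_connected_ksubgraphs(g: nx.Graph, k: int) -> set[frozenset]:
    """All connected k-subsets by brute force over C(n, k) subsets."""
    return {
        frozenset(sub)
        for sub in combinations(g.nodes, k)
        if nx.is_connected(g.subgraph(sub))
    }


def oracle_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    from math import comb

    total = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / total
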