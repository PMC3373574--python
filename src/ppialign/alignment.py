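"""The weighted alignment graph and its edge scoring.

Nodes of the alignment graph are the composite (ortholog-pair) nodes of the
union graph; an edge connects two composite nodes whenever the union graph
contains at least one valid path of length <= 2 between them. Each edge is
scored by a Jaccard-style *extended local interactome* statistic combining a
direct and an indirect (length-2 path) contribution:

    c_dir = w1(a,b) / (S1(a) + S1(b) - w1(a,b))        if w1(a,b) > 0
    c_ind = P2(a,b) / (S2(a) + S2(b) - P2(a,b))        if P2(a,b) > 0
    score = c_dir + c_ind                              in [0, 2]

where ``w1(a,b)`` is the direct union-edge score, ``P2(a,b)`` the total score
of valid length-2 paths a-x-b (a path scores the sum of its two union-edge
scores), and ``S_k(n)`` the total score of direct edges / valid length-2 paths
from ``n`` to *composite* endpoints. The denominators implement union
semantics over the two endpoints' path collections: shared a-b path mass is
counted once. A length-2 path is *spurious* — and ignored everywhere — unless
a single species supports both of its edges ("both"-supported edges satisfy
either species).

After scoring, edges incident to ortholog-multiplets are rank-corrected
(score divided by its rank among competing associations) and the graph is
pruned by a local threshold rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .union import Node, UnionGraph, is_composite

logger = logging.getLogger(__name__)

__all__ = [
    "EliBreakdown",
    "AlignmentGraph",
    "PruneConfig",
    "valid_paths",
    "eli_score",
    "build_alignment_graph",
    "correct_multiortholog",
    "prune",
]


@dataclass(frozen=True)
class EliBreakdown:
    """Components of one alignment-graph edge score."""

    direct_numerator: float  # w1(a,b)
    direct_denominator: float  # S1(a) + S1(b) - w1(a,b)
    indirect_numerator: float  # P2(a,b)
    indirect_denominator: float  # S2(a) + S2(b) - P2(a,b)
    c_dir: float
    c_ind: float
    total: float
    path_count_len2: int


@dataclass
class PruneConfig:
    """Local pruning threshold t in (0, 1); 0.5 is the production default,
    results are stable for t in roughly 0.3-0.7."""

    t: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.t < 1.0:
            raise ValueError(f"pruning threshold t must lie in (0, 1), got {self.t}")


@dataclass
class AlignmentGraph:
    """Composite-node graph with scored (and optionally corrected/pruned) edges.

    Node attribute ``node_score`` is the homology confidence. Edge attributes:
    ``eli`` (:class:`EliBreakdown`), ``score`` (= eli.total) and ``corrected``
    (after multi-ortholog correction; initially equal to ``score``).
    """

    graph: nx.Graph
    species: tuple[str, str]

    def copy(self) -> "AlignmentGraph":
        return AlignmentGraph(self.graph.copy(), self.species)

    def node_score(self, node: Node) -> float:
        return self.graph.nodes[node]["node_score"]


def _compatible(sup_a: frozenset[int], sup_b: frozenset[int]) -> bool:
    # the spurious-path rule: some single species must support both edges
    return bool(sup_a & sup_b)


def valid_paths(
    ug: UnionGraph, a: Node, b: Node
) -> tuple[float, list[tuple[Node, float]]]:
    """Direct union-edge score w1(a,b) and all non-spurious length-2 paths.

    Returns ``(w1, [(intermediate, path_score), ...])``; ``w1`` is 0 when no
    direct edge exists. Each path scores the sum of its two union-edge scores.
    """
    if a == b or not (is_composite(a) and is_composite(b)):
        raise ValueError("valid_paths requires two distinct composite nodes")
    g = ug.graph
    w1 = g[a][b]["score"] if g.has_edge(a, b) else 0.0
    # enumerate from the lexicographically smaller endpoint so that the
    # floating-point summation order (hence the score) is exactly symmetric
    lo, hi = (a, b) if a <= b else (b, a)
    paths = []
    for x in g[lo]:
        if x == hi or not g.has_edge(x, hi):
            continue
        ea, eb = g[lo][x], g[x][hi]
        if _compatible(ea["sup"], eb["sup"]):
            paths.append((x, ea["score"] + eb["score"]))
    return w1, paths


def _direct_mass(ug: UnionGraph, n: Node) -> float:
    """S1(n): total score of direct union edges from n to composite nodes."""
    g = ug.graph
    return sum(g[n][c]["score"] for c in g[n] if is_composite(c))


def _indirect_mass(ug: UnionGraph, n: Node) -> float:
    """S2(n): total score of valid length-2 paths from n to composite nodes."""
    g = ug.graph
    total = 0.0
    for x in g[n]:
        ea = g[n][x]
        for c in g[x]:
            if c == n or not is_composite(c):
                continue
            eb = g[x][c]
            if _compatible(ea["sup"], eb["sup"]):
                total += ea["score"] + eb["score"]
    return total


def _breakdown(
    w1: float, p2: float, s1a: float, s1b: float, s2a: float, s2b: float, n_paths: int
) -> EliBreakdown:
    d_dir = s1a + s1b - w1
    d_ind = s2a + s2b - p2
    c_dir = w1 / d_dir if w1 > 0.0 and d_dir > 0.0 else 0.0
    c_ind = p2 / d_ind if p2 > 0.0 and d_ind > 0.0 else 0.0
    return EliBreakdown(
        direct_numerator=w1,
        direct_denominator=d_dir,
        indirect_numerator=p2,
        indirect_denominator=d_ind,
        c_dir=c_dir,
        c_ind=c_ind,
        total=c_dir + c_ind,
        path_count_len2=n_paths,
    )


def eli_score(ug: UnionGraph, a: Node, b: Node) -> EliBreakdown:
    """Score one composite pair directly from the union graph."""
    w1, paths = valid_paths(ug, a, b)
    p2 = sum(s for _, s in paths)
    return _breakdown(
        w1,
        p2,
        _direct_mass(ug, a),
        _direct_mass(ug, b),
        _indirect_mass(ug, a),
        _indirect_mass(ug, b),
        len(paths),
    )


def build_alignment_graph(ug: UnionGraph) -> AlignmentGraph:
    """Score every composite pair at union-graph distance <= 2.

    Candidate pairs are found by scanning 1- and 2-hop neighborhoods (never
    all pairs); isolated composite nodes are dropped.
    """
    g = ug.graph
    w1: dict[tuple[Node, Node], float] = {}
    s1: dict[Node, float] = {}
    for a, b, d in g.edges(data=True):
        if is_composite(a) and is_composite(b):
            key = (a, b) if a <= b else (b, a)
            w1[key] = d["score"]
            s1[a] = s1.get(a, 0.0) + d["score"]
            s1[b] = s1.get(b, 0.0) + d["score"]

    p2: dict[tuple[Node, Node], float] = {}
    n_paths: dict[tuple[Node, Node], int] = {}
    s2: dict[Node, float] = {}
    for x in g:
        nbrs = [(n, g[x][n]) for n in g[x]]
        for (a, ea), (b, eb) in combinations(nbrs, 2):
            if not (is_composite(a) and is_composite(b)):
                continue
            if not _compatible(ea["sup"], eb["sup"]):
                continue
            score = ea["score"] + eb["score"]
            key = (a, b) if a <= b else (b, a)
            p2[key] = p2.get(key, 0.0) + score
            n_paths[key] = n_paths.get(key, 0) + 1
            s2[a] = s2.get(a, 0.0) + score
            s2[b] = s2.get(b, 0.0) + score

    ag = nx.Graph()
    for key in w1.keys() | p2.keys():
        a, b = key
        eli = _breakdown(
            w1.get(key, 0.0),
            p2.get(key, 0.0),
            s1.get(a, 0.0),
            s1.get(b, 0.0),
            s2.get(a, 0.0),
            s2.get(b, 0.0),
            n_paths.get(key, 0),
        )
        if eli.total > 0.0:
            ag.add_edge(a, b, eli=eli, score=eli.total, corrected=eli.total)
    for n in ag.nodes:
        ag.nodes[n]["node_score"] = g.nodes[n]["conf"]
    logger.info(
        "alignment graph: %d nodes, %d edges", ag.number_of_nodes(), ag.number_of_edges()
    )
    return AlignmentGraph(ag, ug.species)


def correct_multiortholog(ag: AlignmentGraph) -> AlignmentGraph:
    """Rank-correct edges competing for the same underlying protein.

    For each node x and each group of >=2 neighbors sharing one underlying
    protein of a species (multiple associations of that protein), the edges
    (x, a_i) are ranked by score descending (ties by lexicographic node id)
    and divided by their rank. An edge grouped several ways (either species,
    either endpoint) is divided once, by the maximum of its ranks, so the
    top-ranked edge of every group is left unchanged. Applied before pruning.
    """
    out = ag.copy()
    g = out.graph
    divisor: dict[frozenset[Node], int] = {}
    for x in g:
        for sidx in (1, 2):
            groups: dict[str, list[Node]] = {}
            for nb in g[x]:
                groups.setdefault(nb[sidx], []).append(nb)
            for members in groups.values():
                if len(members) < 2:
                    continue
                members.sort(key=lambda nb: (-g[x][nb]["score"], nb))
                for rank, nb in enumerate(members, 1):
                    key = frozenset((x, nb))
                    divisor[key] = max(divisor.get(key, 1), rank)
    for u, v, d in g.edges(data=True):
        d["corrected"] = d["score"] / divisor.get(frozenset((u, v)), 1)
    return out


def prune(ag: AlignmentGraph, cfg: PruneConfig | float = 0.5) -> AlignmentGraph:
    """Keep only locally high-scoring edges.

    With m(u) the maximum corrected score incident to u *before any deletion*,
    an edge (u, v) is deleted when corrected < t*m(u) or corrected < t*m(v)
    (single-pass semantics; maxima are not recomputed). Nodes left isolated
    are removed.
    """
    if not isinstance(cfg, PruneConfig):
        cfg = PruneConfig(float(cfg))
    t = cfg.t
    g = ag.graph
    m = {
        u: max((g[u][v]["corrected"] for v in g[u]), default=0.0) for u in g
    }
    kept = nx.Graph()
    n_before = g.number_of_edges()
    for u, v, d in g.edges(data=True):
        if d["corrected"] >= t * m[u] and d["corrected"] >= t * m[v]:
            kept.add_edge(u, v, **d)
    for n in kept.nodes:
        kept.nodes[n]["node_score"] = g.nodes[n]["node_score"]
    logger.info(
        "pruning (t=%.2f): %d -> %d edges, %d of %d nodes removed",
        t,
        n_before,
        kept.number_of_edges(),
        g.number_of_nodes() - kept.number_of_nodes(),
        g.number_of_nodes(),
    )
    return AlignmentGraph(kept, ag.species)
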