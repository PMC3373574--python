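"""Alignment-graph scoring: path validity, edge score components,
multi-ortholog correction and local pruning."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

import ppialign as pa
from ppialign.alignment import AlignmentGraph

from _util import (
    oracle_eli_scores,
    random_alignment_graph,
    random_union_graph,
)


def _triangle_union(sup_ax, sup_xb, s_ax=2.0, s_xb=0.5):
    """Hand-built union graph a - x - b with chosen supports."""
    g = nx.Graph()
    a, b, x = ("c", "a1", "a2"), ("c", "b1", "b2"), ("s", "y", "x1")
    g.add_node(a, conf=1.0)
    g.add_node(b, conf=1.0)
    g.add_node(x)
    for (u, v), sup, s in (((a, x), sup_ax, s_ax), ((x, b), sup_xb, s_xb)):
        g.add_edge(u, v, sup=frozenset(sup), score=s,
                   s1=s if 1 in sup else 0.0, s2=s if 2 in sup else 0.0,
                   support="both" if len(sup) == 2 else f"sp{next(iter(sup))}")
    return pa.UnionGraph(g, ("y", "f")), a, b, x


class TestValidPaths:
    def test_direct_conserved_edge_no_intermediates(self, toy_conserved_pair):
        ug = pa.build_union_graph(*toy_conserved_pair)
        w1, paths = pa.valid_paths(ug, ("c", "u1", "u2"), ("c", "v1", "v2"))
        assert w1 == pytest.approx(0.7) and paths == []

    def test_cross_species_only_path_is_spurious(self):
        ug, a, b, _ = _triangle_union({1}, {2})
        assert pa.valid_paths(ug, a, b) == (0.0, [])

    def test_both_support_satisfies_either_species(self):
        ug, a, b, x = _triangle_union({1, 2}, {1})
        w1, paths = pa.valid_paths(ug, a, b)
        assert w1 == 0.0
        assert paths == [(x, pytest.approx(2.5))]

    def test_requires_distinct_composite_nodes(self):
        ug, a, b, x = _triangle_union({1}, {1})
        with pytest.raises(ValueError):
            pa.valid_paths(ug, a, a)
        with pytest.raises(ValueError):
            pa.valid_paths(ug, a, x)


class TestEliScore:
    def test_isolated_conserved_pair_scores_one(self, toy_conserved_pair):
        ug = pa.build_union_graph(*toy_conserved_pair)
        eli = pa.eli_score(ug, ("c", "u1", "u2"), ("c", "v1", "v2"))
        assert eli.c_dir == pytest.approx(1.0)
        assert eli.c_ind == 0.0
        assert eli.total == pytest.approx(1.0)

    def test_no_valid_path_means_zero(self):
        ug, a, b, _ = _triangle_union({1}, {2})
        assert pa.eli_score(ug, a, b).total == 0.0

    def test_matches_oracle_on_random_union_graphs(self, rng):
        for _ in range(30):
            ug = random_union_graph(rng)
            expected = oracle_eli_scores(ug)
            for pair, total in expected.items():
                a, b = sorted(pair)
                assert pa.eli_score(ug, a, b).total == pytest.approx(
                    total, abs=1e-12
                )

    def test_symmetry_and_bounds(self, rng):
        for _ in range(10):
            ug = random_union_graph(rng)
            comps = sorted(ug.composites)
            for a, b in combinations(comps[:8], 2):
                e1 = pa.eli_score(ug, a, b)
                e2 = pa.eli_score(ug, b, a)
                assert e1.total == e2.total
                assert 0.0 <= e1.c_dir <= 1.0
                assert 0.0 <= e1.c_ind <= 1.0
                assert e1.total == pytest.approx(e1.c_dir + e1.c_ind)

    def test_extra_indirect_path_never_decreases_c_ind(self):
        # grow the number of conserved a-x_i-b paths; c_ind must be monotone
        prev = -1.0
        for n_paths in (1, 2, 3):
            e1 = [("u1", f"x{i}", 0.6) for i in range(n_paths)]
            e1 += [(f"x{i}", "v1", 0.6) for i in range(n_paths)]
            e2 = [("u2", f"z{i}", 0.6) for i in range(n_paths)]
            e2 += [(f"z{i}", "v2", 0.6) for i in range(n_paths)]
            net1 = pa.WeightedNetwork.from_edges("y", e1)
            net2 = pa.WeightedNetwork.from_edges("f", e2)
            hom = pa.HomologyMap.from_records(
                [("u1", "u2", 1.0), ("v1", "v2", 1.0)]
                + [(f"x{i}", f"z{i}", 1.0) for i in range(n_paths)]
            )
            ug = pa.build_union_graph(net1, net2, hom)
            eli = pa.eli_score(ug, ("c", "u1", "u2"), ("c", "v1", "v2"))
            assert eli.c_ind >= prev
            prev = eli.c_ind


class TestBuildAlignmentGraph:
    def test_toy_has_single_unit_edge(self, toy_conserved_pair):
        ag = pa.build_alignment_graph(pa.build_union_graph(*toy_conserved_pair))
        assert ag.graph.number_of_edges() == 1
        (_, _, d), = ag.graph.edges(data=True)
        assert d["score"] == pytest.approx(1.0)

    def test_distance_three_pair_gets_no_edge(self):
        # chain a - m1 - m2 - b of conserved edges: a,b at distance 3
        pairs = [("a", "m"), ("m", "n"), ("n", "b")]
        net1 = pa.WeightedNetwork.from_edges(
            "y", [(f"{u}1", f"{v}1", 0.5) for u, v in pairs]
        )
        net2 = pa.WeightedNetwork.from_edges(
            "f", [(f"{u}2", f"{v}2", 0.5) for u, v in pairs]
        )
        hom = pa.HomologyMap.from_records(
            [(f"{p}1", f"{p}2", 1.0) for p in "amnb"]
        )
        ag = pa.build_alignment_graph(pa.build_union_graph(net1, net2, hom))
        assert not ag.graph.has_edge(("c", "a1", "a2"), ("c", "b1", "b2"))

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(25):
            ug = random_union_graph(rng, n1=12, n2=12, n_hom=10)
            ag = pa.build_alignment_graph(ug)
            expected = oracle_eli_scores(ug)
            got = {
                frozenset((a, b)): d["score"]
                for a, b, d in ag.graph.edges(data=True)
            }
            assert got.keys() == expected.keys()
            for pair, total in expected.items():
                assert got[pair] == pytest.approx(total, abs=1e-12)


class TestMultiorthologCorrection:
    def _star(self, scores, shared_species1=True):
        g = nx.Graph()
        x = ("c", "px", "qx")
        g.add_node(x, node_score=1.0)
        for i, s in enumerate(scores):
            nb = ("c", "pa" if shared_species1 else f"p{i}",
                  f"q{i}" if shared_species1 else "qa")
            nb = ("c", nb[1], nb[2])
            g.add_node(nb, node_score=1.0)
            g.add_edge(x, nb, score=s, corrected=s)
        return AlignmentGraph(g, ("sp1", "sp2"))

    def test_rank_division_within_group(self):
        ag = pa.correct_multiortholog(self._star([0.9, 0.6, 0.3]))
        corrected = sorted(
            (d["corrected"] for _, _, d in ag.graph.edges(data=True)),
            reverse=True,
        )
        assert corrected == pytest.approx([0.9, 0.3, 0.1])

    def test_group_of_one_unchanged(self):
        ag = pa.correct_multiortholog(self._star([0.7], shared_species1=False))
        (_, _, d), = ag.graph.edges(data=True)
        assert d["corrected"] == 0.7

    def test_tie_broken_by_node_id(self):
        ag = pa.correct_multiortholog(self._star([0.5, 0.5]))
        x = ("c", "px", "qx")
        by_nb = {
            (u if u != x else v): d["corrected"]
            for u, v, d in ag.graph.edges(data=True)
        }
        assert by_nb[("c", "pa", "q0")] == pytest.approx(0.5)
        assert by_nb[("c", "pa", "q1")] == pytest.approx(0.25)

    def test_never_increases_and_top_edge_kept(self, rng):
        for _ in range(20):
            ag = random_alignment_graph(rng, 14, 0.3, shared_protein_prob=0.6)
            out = pa.correct_multiortholog(ag)
            g, og = ag.graph, out.graph
            assert set(g.edges) == set(og.edges)
            for u, v in g.edges:
                assert og[u][v]["corrected"] <= g[u][v]["score"] + 1e-12
            # brute-force recomputation of the expected divisor
            for u, v in g.edges:
                div = 1
                for x, other in ((u, v), (v, u)):
                    for sidx in (1, 2):
                        group = [
                            nb for nb in g[x] if nb[sidx] == other[sidx]
                        ]
                        if len(group) < 2:
                            continue
                        group.sort(key=lambda nb: (-g[x][nb]["score"], nb))
                        div = max(div, group.index(other) + 1)
                assert og[u][v]["corrected"] == pytest.approx(
                    g[u][v]["score"] / div
                )


class TestPrune:
    def _path_scores(self, scores):
        """Chain u - n0 - n1 ... with given corrected scores on a hub node."""
        g = nx.Graph()
        hub = ("c", "h", "h")
        g.add_node(hub, node_score=1.0)
        for i, s in enumerate(scores):
            nb = ("c", f"n{i}", f"n{i}")
            g.add_node(nb, node_score=1.0)
            g.add_edge(hub, nb, score=s, corrected=s)
        return AlignmentGraph(g, ("sp1", "sp2"))

    def test_threshold_rule_on_hub(self):
        ag = pa.prune(self._path_scores([1.0, 0.6, 0.3]), 0.5)
        kept = [d["corrected"] for _, _, d in ag.graph.edges(data=True)]
        assert sorted(kept) == pytest.approx([0.6, 1.0])

    def test_equal_scores_keep_everything(self):
        ag = pa.prune(self._path_scores([0.4, 0.4, 0.4]), 0.5)
        assert ag.graph.number_of_edges() == 3

    def test_failed_leaf_removed_entirely(self):
        ag = pa.prune(self._path_scores([1.0, 0.2]), 0.5)
        assert ("c", "n1", "n1") not in ag.graph

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            pa.PruneConfig(0.0)
        with pytest.raises(ValueError):
            pa.PruneConfig(1.0)

    def test_survivors_satisfy_pre_pruning_maxima(self, rng):
        for _ in range(20):
            ag = random_alignment_graph(rng, 16, 0.3)
            t = float(rng.uniform(0.3, 0.7))
            m = {
                u: max(
                    (ag.graph[u][v]["corrected"] for v in ag.graph[u]),
                    default=0.0,
                )
                for u in ag.graph
            }
            out = pa.prune(ag, t)
            for u, v, d in out.graph.edges(data=True):
                assert d["corrected"] >= t * m[u] - 1e-12
                assert d["corrected"] >= t * m[v] - 1e-12
            # single-pass semantics: deletions never cascade
            for u, v, d in ag.graph.edges(data=True):
                if d["corrected"] >= t * m[u] and d["corrected"] >= t * m[v]:
                    assert out.graph.has_edge(u, v)
            assert not [n for n in out.graph if out.graph.degree(n) == 0]
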