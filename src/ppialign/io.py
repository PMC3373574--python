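"""Tabular input/output and the normalized domain containers.

Three external formats are read, all tab/whitespace-delimited UTF-8 text with
``#``-prefixed comment lines ignored:

* weighted edge lists (``idA  idB  reliability``) for the per-species PPI
  networks, reliabilities in ``(0, 1]``;
* a scored homology table (``id_species1  id_species2  confidence``),
  many-to-many, Inparanoid-style;
* complex catalogs, one complex per line (``complex_id  member  member ...``),
  CYC2008/CORUM-style.

Discovered modules are written as a TSV summary plus a JSON sidecar carrying
full expansion provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "WeightedNetwork",
    "HomologyMap",
    "ComplexCatalog",
    "ModuleRecord",
    "read_network",
    "read_homology",
    "read_complexes",
    "read_modules",
    "write_network",
    "write_homology",
    "write_complexes",
    "write_modules",
]


class ParseError(ValueError):
    """A malformed input row (wrong column count, non-numeric field)."""


class ValidationError(ValueError):
    """A well-formed row carrying an out-of-range value."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class WeightedNetwork:
    """One species' PPI graph with per-edge reliability scores in (0, 1].

    Undirected, no self-loops, no duplicate pairs. Protein identifiers are
    opaque, case-sensitive strings; no identifier mapping is performed.
    """

    species: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        species: str,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "WeightedNetwork":
        """Build a normalized network from (u, v, weight) triples.

        Duplicate unordered pairs are merged keeping the maximum weight;
        self-loops are dropped with a logged warning; weights outside (0, 1]
        raise :class:`ValidationError`.
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, w in edges:
            w = float(w)
            if not 0.0 < w <= 1.0:
                raise ValidationError(
                    f"reliability {w!r} for edge ({u}, {v}) outside (0, 1]"
                )
            if u == v:
                logger.warning("dropping self-loop on %s in network %s", u, species)
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
        return cls(species, g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["weight"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class HomologyMap:
    """Scored, many-to-many cross-species protein associations.

    ``records`` maps an ordered pair (protein_species1, protein_species2) to
    a confidence in (0, 1].
    """

    records: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "HomologyMap":
        out: dict[tuple[str, str], float] = {}
        for p1, p2, c in records:
            c = float(c)
            if not 0.0 < c <= 1.0:
                raise ValidationError(
                    f"confidence {c!r} for pair ({p1}, {p2}) outside (0, 1]"
                )
            key = (p1, p2)
            out[key] = max(out.get(key, 0.0), c)
        return cls(out)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for (p1, p2), c in self.records.items():
            yield p1, p2, c

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ComplexCatalog:
    """Reference protein complexes of a single species: id -> member set."""

    complexes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.complexes)

    def items(self):
        return self.complexes.items()

    def of_size(self, lo: int, hi: int | None = None) -> dict[str, frozenset[str]]:
        """Complexes whose member count lies in [lo, hi] (hi=None: no cap)."""
        return {
            cid: m
            for cid, m in self.complexes.items()
            if len(m) >= lo and (hi is None or len(m) <= hi)
        }


@dataclass(frozen=True)
class ModuleRecord:
    """A module as read back from a modules TSV file."""

    id: str
    score: float
    node_score: float
    edge_score: float
    seed_nodes: tuple[tuple[str, str], ...]
    node_set: tuple[tuple[str, str], ...]

    @property
    def proteins1(self) -> frozenset[str]:
        return frozenset(p1 for p1, _ in self.node_set)

    @property
    def proteins2(self) -> frozenset[str]:
        return frozenset(p2 for _, p2 in self.node_set)

    @property
    def n_nodes(self) -> int:
        return len(self.node_set)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_rows(path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def _read_scored_pairs(path, what: str) -> list[tuple[str, str, float]]:
    rows: list[tuple[str, str, float]] = []
    first_data = True
    for lineno, fields in _data_rows(path):
        if len(fields) < 3:
            raise ParseError(
                f"{path}, line {lineno}: expected >=3 columns, got {len(fields)}"
            )
        try:
            w = float(fields[2])
        except ValueError:
            if first_data:
                # optional header line, detected by a non-numeric third field
                first_data = False
                continue
            raise ParseError(
                f"{path}, line {lineno}: non-numeric {what} {fields[2]!r}"
            ) from None
        first_data = False
        if not 0.0 < w <= 1.0:
            raise ValidationError(
                f"{path}, line {lineno}: {what} {w} outside (0, 1]"
            )
        rows.append((fields[0], fields[1], w))
    return rows


def read_network(path, species_label: str) -> WeightedNetwork:
    """Read a TSV edge list (idA, idB, reliability) into a normalized network."""
    return WeightedNetwork.from_edges(
        species_label, _read_scored_pairs(path, "reliability")
    )


def read_homology(path) -> HomologyMap:
    """Read a TSV homology table (id_species1, id_species2, confidence)."""
    return HomologyMap.from_records(_read_scored_pairs(path, "confidence"))


def read_complexes(path) -> ComplexCatalog:
    """Read a catalog: one complex per line, ``complex_id member member ...``."""
    complexes: dict[str, frozenset[str]] = {}
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise ParseError(
                f"{path}, line {lineno}: complex line needs an id and >=1 member"
            )
        cid, members = fields[0], frozenset(fields[1:])
        if cid in complexes:
            raise ParseError(f"{path}, line {lineno}: duplicate complex id {cid!r}")
        complexes[cid] = members
    return ComplexCatalog(complexes)


def read_modules(path) -> list[ModuleRecord]:
    """Read back a modules TSV written by :func:`write_modules`."""
    out: list[ModuleRecord] = []
    for lineno, fields in _data_rows(path):
        if len(fields) < 6:
            raise ParseError(f"{path}, line {lineno}: expected 6 columns")
        mid, score, nsc, esc, seed_tok, node_tok = fields[:6]
        try:
            out.append(
                ModuleRecord(
                    id=mid,
                    score=float(score),
                    node_score=float(nsc),
                    edge_score=float(esc),
                    seed_nodes=_parse_pairs(seed_tok),
                    node_set=_parse_pairs(node_tok),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from None
    return out


def _parse_pairs(token: str) -> tuple[tuple[str, str], ...]:
    pairs = []
    for item in token.split(";"):
        p1, sep, p2 = item.partition("|")
        if not sep:
            raise ValueError(f"malformed composite node token {item!r}")
        pairs.append((p1, p2))
    return tuple(pairs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_network(net: WeightedNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# species: {net.species}\n")
        fh.write("# protein_a\tprotein_b\treliability\n")
        for u, v, w in sorted(
            (tuple(sorted((a, b))) + (w,) for a, b, w in net.edges())
        ):
            fh.write(f"{u}\t{v}\t{w:.6g}\n")


def write_homology(hom: HomologyMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_species1\tprotein_species2\tconfidence\n")
        for p1, p2, c in sorted(hom):
            fh.write(f"{p1}\t{p2}\t{c:.6g}\n")


def write_complexes(catalog: ComplexCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# complex_id\tmembers...\n")
        for cid in sorted(catalog.complexes):
            members = "\t".join(sorted(catalog.complexes[cid]))
            fh.write(f"{cid}\t{members}\n")


_MODULE_HEADER = (
    "# module_id\tscore\tnode_score\tedge_score\tseed_nodes\tcomposite_nodes\n"
)


def _fmt_pairs(pairs) -> str:
    return ";".join(f"{p1}|{p2}" for p1, p2 in sorted(pairs))


def write_modules(modules: Sequence, path) -> None:
    """Write modules as TSV plus a ``<path>.json`` provenance sidecar.

    Ordering is deterministic: score descending, ties broken by the
    lexicographically smallest composite node, so re-running on identical
    input produces byte-identical output.
    """
    def node_pairs(m):
        return sorted((n[1], n[2]) for n in m.node_set)

    ordered = sorted(modules, key=lambda m: (-m.score, node_pairs(m)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MODULE_HEADER)
        for m in ordered:
            fh.write(
                f"{m.id}\t{m.score:.6f}\t{m.node_score:.6f}\t{m.edge_score:.6f}\t"
                f"{_fmt_pairs((n[1], n[2]) for n in m.seed_nodes)}\t"
                f"{_fmt_pairs(node_pairs(m))}\n"
            )
    sidecar = {
        "modules": [
            {
                "id": m.id,
                "score": m.score,
                "node_score": m.node_score,
                "edge_score": m.edge_score,
                "seed": [list(p) for p in sorted((n[1], n[2]) for n in m.seed_nodes)],
                "nodes": [list(p) for p in node_pairs(m)],
                "steps": [
                    {
                        "iteration": it,
                        "added_subgraphs": [
                            sorted(f"{n[1]}|{n[2]}" for n in sg) for sg in subgraphs
                        ],
                    }
                    for it, subgraphs in m.steps
                ],
            }
            for m in ordered
        ]
    }
    with open(f"{path}.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")
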