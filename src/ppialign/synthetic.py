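"""Paired-network generator with planted conserved complexes.

The generator emulates the data regime the aligner is designed for: two
species' weighted PPI networks sharing a set of conserved protein complexes,
each species observing the conserved interactions through an independent
false-negative filter (the main pathology of real interactome data), plus an
Erdos-Renyi background of unreliable interactions and a noisy many-to-many
orthology map (a 1-1 true core diluted with spurious cross-pairs of lower
confidence). Reliabilities are Beta-distributed, with separate shapes for
conserved and background edges. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .evaluation import prf1
from .io import ComplexCatalog, HomologyMap, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_paired_networks",
    "catalog_from_truth",
    "recovery_report",
]

_MIN_W = 1e-6  # Beta draws of exactly 0 would violate the (0, 1] contract


@dataclass
class SimConfig:
    """Benchmark generating conditions.

    Defaults define the standard desk-scale benchmark: 300 proteins per
    species, 10 planted complexes of 6-10 proteins, within-complex edge
    probability 0.6 thinned by a per-species false-negative rate of 0.2,
    background density 0.005, and 30% spurious homology pairs.
    """

    n_proteins: int = 300
    n_complexes: int = 10
    complex_size_min: int = 6
    complex_size_max: int = 10
    p_in: float = 0.6
    p_out: float = 0.005
    false_negative_rate: float = 0.2
    ortholog_noise: float = 0.3
    true_reliability: tuple[float, float] = (8.0, 2.0)  # Beta shapes
    background_reliability: tuple[float, float] = (2.0, 6.0)
    rng_seed: int = 0
    species: tuple[str, str] = ("sp1", "sp2")

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_complexes < 0:
            raise ValueError("n_proteins must be >= 1 and n_complexes >= 0")
        if not 2 <= self.complex_size_min <= self.complex_size_max:
            raise ValueError("complex sizes must satisfy 2 <= min <= max")
        if self.n_complexes * self.complex_size_max > self.n_proteins:
            raise ValueError("planted complexes cannot exceed the protein pool")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.false_negative_rate <= 1.0:
            raise ValueError("false_negative_rate must lie in [0, 1]")
        if self.ortholog_noise < 0.0:
            raise ValueError("ortholog_noise must be >= 0")
        for shapes in (self.true_reliability, self.background_reliability):
            if min(shapes) <= 0.0:
                raise ValueError("Beta shapes must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulation."""

    complexes: dict[str, tuple[frozenset[str], frozenset[str]]] = field(
        default_factory=dict
    )
    core_pairs: frozenset[tuple[str, str]] = frozenset()
    spurious_pairs: frozenset[tuple[str, str]] = frozenset()


def _beta(rng: np.random.Generator, shapes: tuple[float, float], n: int) -> np.ndarray:
    return np.maximum(rng.beta(shapes[0], shapes[1], size=n), _MIN_W)


def simulate_paired_networks(
    cfg: SimConfig,
) -> tuple[WeightedNetwork, WeightedNetwork, HomologyMap, SimTruth]:
    """Draw one paired-network instance.

    Conserved within-complex edges are drawn once with ``p_in`` and then
    thinned independently per species with the false-negative rate, so the
    two networks observe overlapping but unequal slices of each complex.
    Background edges are independent per species. The homology map is the
    1-1 core over all proteins plus ``ortholog_noise * n`` spurious random
    cross-pairs drawn from the background confidence distribution.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_proteins
    sp1, sp2 = cfg.species
    names1 = [f"{sp1}_{i:04d}" for i in range(n)]
    names2 = [f"{sp2}_{i:04d}" for i in range(n)]

    # planted complexes: disjoint member index sets
    sizes = rng.integers(
        cfg.complex_size_min, cfg.complex_size_max + 1, size=cfg.n_complexes
    )
    perm = rng.permutation(n)
    truth = SimTruth()
    member_of: dict[int, int] = {}
    offset = 0
    for c, size in enumerate(sizes):
        idx = sorted(int(i) for i in perm[offset : offset + size])
        offset += size
        for i in idx:
            member_of[i] = c
        truth.complexes[f"K{c + 1:03d}"] = (
            frozenset(names1[i] for i in idx),
            frozenset(names2[i] for i in idx),
        )

    edges1: list[tuple[str, str, float]] = []
    edges2: list[tuple[str, str, float]] = []
    # conserved within-complex interactions, thinned per species
    cpx_pairs = [
        (i, j)
        for i, j in combinations(sorted(member_of), 2)
        if member_of[i] == member_of[j]
    ]
    if cpx_pairs:
        conserved = rng.random(len(cpx_pairs)) < cfg.p_in
        keep1 = conserved & (rng.random(len(cpx_pairs)) >= cfg.false_negative_rate)
        keep2 = conserved & (rng.random(len(cpx_pairs)) >= cfg.false_negative_rate)
        w1 = _beta(rng, cfg.true_reliability, len(cpx_pairs))
        w2 = _beta(rng, cfg.true_reliability, len(cpx_pairs))
        for k, (i, j) in enumerate(cpx_pairs):
            if keep1[k]:
                edges1.append((names1[i], names1[j], float(w1[k])))
            if keep2[k]:
                edges2.append((names2[i], names2[j], float(w2[k])))

    # background: every pair not inside one planted complex
    bg_pairs = [
        (i, j)
        for i, j in combinations(range(n), 2)
        if member_of.get(i, -1) != member_of.get(j, -2)
    ]
    draw1 = rng.random(len(bg_pairs)) < cfg.p_out
    draw2 = rng.random(len(bg_pairs)) < cfg.p_out
    bw1 = _beta(rng, cfg.background_reliability, len(bg_pairs))
    bw2 = _beta(rng, cfg.background_reliability, len(bg_pairs))
    for k, (i, j) in enumerate(bg_pairs):
        if draw1[k]:
            edges1.append((names1[i], names1[j], float(bw1[k])))
        if draw2[k]:
            edges2.append((names2[i], names2[j], float(bw2[k])))

    net1 = WeightedNetwork.from_edges(sp1, edges1, nodes=names1)
    net2 = WeightedNetwork.from_edges(sp2, edges2, nodes=names2)

    # homology: 1-1 core plus spurious many-to-many noise
    core_conf = _beta(rng, cfg.true_reliability, n)
    records = [(names1[i], names2[i], float(core_conf[i])) for i in range(n)]
    truth.core_pairs = frozenset((names1[i], names2[i]) for i in range(n))
    n_spur = int(round(cfg.ortholog_noise * n))
    spurious: set[tuple[str, str]] = set()
    while len(spurious) < n_spur:
        i, j = (int(v) for v in rng.integers(0, n, size=2))
        if i == j:
            continue
        spurious.add((names1[i], names2[j]))
    spur_conf = _beta(rng, cfg.background_reliability, len(spurious))
    for k, (p1, p2) in enumerate(sorted(spurious)):
        records.append((p1, p2, float(spur_conf[k])))
    truth.spurious_pairs = frozenset(spurious)
    hom = HomologyMap.from_records(records)
    logger.info(
        "simulated %d+%d edges, %d homology records (%d spurious)",
        net1.n_edges,
        net2.n_edges,
        len(hom),
        len(spurious),
    )
    return net1, net2, hom, truth


def catalog_from_truth(truth: SimTruth, species: int) -> ComplexCatalog:
    """The planted complexes as a per-species reference catalog."""
    return ComplexCatalog(
        {cid: sets[species - 1] for cid, sets in truth.complexes.items()}
    )


def recovery_report(modules: Sequence, truth: SimTruth) -> dict:
    """Desk-scale recovery summary against the planted truth.

    Per planted complex the best-matching module is found under the mean of
    the two species' F1 (the complexes are paired by construction); the
    summary reports the matched fractions at F1 > 0.3 and > 0.5, the mean
    best-match F1, and the cross-species mapping accuracy — the fraction of
    module composite nodes that are true-core ortholog pairs.
    """
    per_complex = []
    for cid in sorted(truth.complexes):
        set1, set2 = truth.complexes[cid]
        best = {"complex_id": cid, "best_module_id": None, "f1_sp1": 0.0,
                "f1_sp2": 0.0, "f1_mean": 0.0}
        for m in modules:
            f1s = []
            for proj, ref in ((m.proteins1, set1), (m.proteins2, set2)):
                f1s.append(prf1(proj, ref)[2] if proj else 0.0)
            f1_mean = sum(f1s) / 2
            if f1_mean > best["f1_mean"]:
                best.update(
                    best_module_id=m.id,
                    f1_sp1=f1s[0],
                    f1_sp2=f1s[1],
                    f1_mean=f1_mean,
                )
        per_complex.append(best)

    n_nodes = 0
    n_core = 0
    for m in modules:
        for node in m.node_set:
            n_nodes += 1
            if (node[1], node[2]) in truth.core_pairs:
                n_core += 1
    n_cpx = len(per_complex)
    f1_means = [b["f1_mean"] for b in per_complex]
    return {
        "per_complex": per_complex,
        "n_complexes": n_cpx,
        "n_modules": len(list(modules)),
        "mean_best_f1": sum(f1_means) / n_cpx if n_cpx else 0.0,
        "frac_matched_0.3": (
            sum(f > 0.3 for f in f1_means) / n_cpx if n_cpx else 0.0
        ),
        "frac_matched_0.5": (
            sum(f > 0.5 for f in f1_means) / n_cpx if n_cpx else 0.0
        ),
        "mapping_accuracy": n_core / n_nodes if n_nodes else 0.0,
    }
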