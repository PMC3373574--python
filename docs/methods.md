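# Methods

## Problem and model

`ppialign` performs pairwise local alignment of weighted PPI networks. The
underlying model of a conserved complex is *relative* density: a group of
ortholog pairs whose members interact more among themselves than with the
rest of either network. This deliberately avoids requiring dense cliques —
real interactome data are riddled with false negatives, and complexes are
believed to consist of a densely connected core plus more loosely attached
proteins, so a conserved complex may appear sparse (or even edgeless) in one
species while being dense in the other. Two design elements carry that
assumption:

* edge evidence is collected over *all* direct and length-2 paths between
  two ortholog pairs in the union graph, so a missing interaction in one
  species can be compensated by indirect conserved paths; and
* module growth proceeds by whole k-subgraphs rather than single nodes,
  letting the search look one neighborhood beyond the current solution's
  immediate interactors.

## Edge scoring (reconstruction notice)

The score of an alignment-graph edge (a, b) is the sum of a direct and an
indirect contribution, each a Jaccard-style ratio:

    c_dir = w1(a,b) / (S1(a) + S1(b) − w1(a,b))      if w1 > 0, else 0
    c_ind = P2(a,b) / (S2(a) + S2(b) − P2(a,b))      if P2 > 0, else 0

with `w1` the direct union-edge score, `P2` the total score of valid
length-2 paths a–x–b (intermediate simple or composite), and `S_k(n)` the
total mass of the corresponding paths from `n` to any other *composite*
node. Both components lie in [0, 1] because the shared a–b path mass is
counted in both endpoints' totals and subtracted once (union semantics);
an isolated conserved pair therefore scores exactly 1.

Three choices here are **reconstructions** — the printed forms of the
original equations in the source material for this method are typeset as
figures and not recoverable as text — fixed as follows and validated by an
exhaustive path-enumeration oracle in the test suite:

1. a length-2 path scores the **sum** of its two union-edge scores (the
   only reading consistent with the published worked totals, where a
   handful of paths over sub-unit edge weights total well above the path
   count times any product bound);
2. the denominators use the **union** of the two endpoints' path
   collections, `S_k(a) + S_k(b) − numerator`;
3. spurious-path exclusion (below) applies uniformly wherever length-2
   paths are summed, in `P2` and in `S2`.

A length-2 path is *spurious* when no single species supports both of its
edges (a species-1-only edge followed by a species-2-only edge corresponds
to no path in either input network); conserved edges with support from both
species satisfy either requirement. Spurious paths contribute exactly
nothing anywhere.

### Multiple orthologs

Many-to-many homology makes one protein appear in several composite nodes.
For each node x and each group of ≥ 2 neighbors sharing an underlying
protein of one species, the edges (x, a_i) are sorted by score (ties broken
by lexicographic node id) and divided by their rank; an edge caught in
several groups (either species, either endpoint) is divided once by the
maximum of its ranks. Group leaders are untouched and correction never
increases a score. Correction runs before pruning.

### Pruning

With m(u) the maximum corrected score incident to u computed before any
deletion, an edge is deleted when it falls below `t·m(u)` **or** `t·m(v)`.
The rule is local because edge-score magnitudes vary strongly across graph
regions; a global cutoff would gut sparse regions. Single-pass semantics
(maxima are not recomputed as edges disappear) make the operation
deterministic and order-independent. Default `t = 0.5`, the midpoint of the
0.3–0.7 range over which results are stable; exposed as `--prune-t`.

## Seeds and expansion

Connected 4-subgraphs are enumerated exactly once by anchored extension
(each anchor only recruits later-ordered, exclusively-new neighbors — the
standard exact motif-enumeration scheme), streamed with a configurable cap
(default 5×10⁶) against combinatorial explosion. Subgraphs score
`Σ node confidence + Σ corrected edge score`; seeds are the node-disjoint
top scorers under a greedy sweep. Seed eligibility does **not** require a
4-clique: pruned alignment graphs are sparse (average degree often < 2) and
additive edge scoring already privileges denser subgraphs; the stricter
clique reading is available via `--require-clique-seeds`.

Expansion judges every pooled subgraph g sharing ≥ 1 node with the module
snapshot M by its frontier g∖M: W_M sums corrected scores of frontier–M
edges, W_N of frontier–N edges (N = everything outside M ∪ g; within-g
edges count toward neither). g is accepted iff `W_M > tight_factor · W_N`,
strictly — ties reject, so neutrally connected subgraphs are not absorbed.
The degenerate case W_N = 0, W_M > 0 ("tightly connected") is always
accepted; the exact tight-connectivity inequality of the original
formulation is figure-rendered and unrecoverable, so the single comparison
above is the implemented rule, with `--tight-factor` (default 1.0) exposing
a stricter variant. All acceptance decisions within an iteration use the
iteration-start snapshot and all accepted subgraphs join at once, making
results independent of candidate order (asserted by shuffle tests). Growth
is monotone, hence terminates. Modules need ≥ 5 nodes (4-node seed plus at
least one completed expansion step); identical node sets are deduplicated;
modules may overlap. One known behavior of batch addition: a weakly
attached node can "hitchhike" into the module inside a candidate dominated
by strongly attached frontier nodes — this is inherent to judging whole
k-subgraphs and is part of why the method tolerates sparse complex
peripheries.

## Evaluation protocol

* Precision = TP/|module projection|, recall = TP/|complex|, F1 their
  harmonic mean (0 on empty overlap). Per catalog complex of ≥ 4 proteins,
  the best-F1 module is selected (ties: precision, then module id); F1 >
  0.3 flags a high-quality match.
* 2–3 protein complexes are counted recovered when a module of ≤ 20 nodes
  shares ≥ 2 proteins with them.
* Enrichment per (complex, best module): one-sided hypergeometric tail
  with the species' network protein count as the universe;
  Benjamini–Hochberg correction across pairs (the standard choice for
  enrichment lists).
* Connectivity significance: per species, the module projection's induced
  edge count L_obs is compared with R degree-preserving randomizations
  (double edge swaps, 10·|E| attempts per draw, weights traveling with the
  rewired stubs; one continuously evolving chain per species supplies the R
  draws). Z = (L_obs − μ)/σ, with Z = 0 when σ = 0 and L_obs = μ, else
  ±∞ by the sign of the deviation; the module statistic is max(Z₁, Z₂),
  crediting a module that is dense in at least one species. The empirical
  p-value is (r + 1)/(R + 1) with r the number of randomizations whose
  recomputed max-Z reaches the observed one; the +1 smoothing avoids p = 0.
  Because induced edge counts are small integers, ties between observed and
  null statistics are common in sparse networks, which makes these p-values
  conservative (super-uniform) for unstructured node sets — they err toward
  1, never toward significance. Default R = 1000; desk-scale checks use
  R = 200.

## Synthetic benchmark

The generator plants `n_complexes` disjoint complexes over a 1–1 ortholog
core of `n_proteins` per species. Conserved within-complex edges are drawn
once with probability `p_in` and then thinned **independently per species**
with the false-negative rate f — the two networks see overlapping but
unequal slices of each complex, which is precisely the regime the indirect
path evidence is designed for. Background edges are independent
Erdős–Rényi with `p_out` (degree-matched nulls belong to evaluation, not
generation). Reliabilities are Beta-distributed: Beta(8, 2) for conserved
edges and the ortholog core (mean 0.8), Beta(2, 6) for background edges and
the `ortholog_noise·n` spurious homology pairs (mean 0.25) — the noisy
pairs deliberately exercise the multi-ortholog correction. Defaults (the
standard benchmark): 300 proteins/species, 10 complexes of 6–10 proteins,
p_in = 0.6, p_out = 0.005, f = 0.2, noise = 0.3.

What the generator does *not* emulate: scale-free degree structure, hub
proteins, duplication–divergence paralogy, correlated experimental error,
or identifier ambiguity. Passing benchmarks therefore demonstrate the
machinery recovers relatively dense conserved structure under missing-data
noise at realistic sparsity — not performance on any particular organism's
interactome.

## Numerical and determinism choices

* All tie-breaks (edge ranks, seed order, module order) are lexicographic
  on composite-node ids; identical inputs give byte-identical outputs.
* Edge-score symmetry is exact: path sums are always accumulated from the
  lexicographically smaller endpoint.
* Zero denominators in either score component yield a zero component.
* All randomness flows through `numpy.random.default_rng` seeds; the CLI
  exposes `--seed` everywhere, and `--threads` (joblib over seed
  expansions) cannot change results because modules are assembled and
  sorted deterministically afterward.
* Problem sizes used by the shipped checks: oracle ensembles of ≤ 15
  composite nodes, enumeration cross-checks at n ≤ 25, and 10–20 benchmark
  replicates at the default 300-protein scale with R = 200 randomizations —
  sizes at which every exhaustive oracle is exact and the full suite runs
  in a few minutes on one CPU.

## Known limitations

* Exactly two species; no multi-species union graphs.
* Reliabilities are inputs; no expression-based reliability estimation, no
  identifier mapping, no GO-based semantic evaluation (hook point: module
  projections are plain protein sets).
* Paths longer than 2 are ignored by design (they add edges without adding
  quality).
* Subgraph enumeration on dense alignment graphs is capped rather than
  approximated; a truncated enumeration is logged and may miss seeds.
* The three reconstructed formula choices above are validated against
  internal consistency and oracle behavior, not against the original
  binary's output.
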