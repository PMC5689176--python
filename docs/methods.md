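# Methods

## Problem and model

The package reconstructs the subnetwork of a protein interaction
network that most plausibly carries signal from a set of **anchors**
(known process drivers) to a set of **terminals** (observed affected
proteins). The background network is a mixed graph: protein–protein
interactions (PPIs) are undirected; protein–DNA interactions (PDIs,
transcription factor → target) are directed and traversable only in
that direction. Every edge carries a confidence `p ∈ (0, 1]`.

Edge confidences become costs via `c(e) = −ln p`. The transform is the
standard one: it is strictly decreasing, additive along paths, and maps
confidence 1 to cost 0, so a minimum-cost path is a maximum-likelihood
path under edge independence. Confidence 0 is rejected rather than
clamped (an interaction believed impossible should not be in the
network); confidence exactly 1 is allowed.

### The anchored objective

Good reconstructions should be small (parsimony) *and* explain each
terminal by a high-likelihood route. These goals conflict — a tree of
shared trunks is small but lengthens individual paths — so they are
combined as a convex trade-off. With a virtual super-root `r` joined to
every anchor by a zero-cost edge (for a single anchor, the anchor
itself is the root):

    f(H) = α · Σ_{e∈H} c(e) + (1−α) · Σ_{t∈T} d_H(r, t)

`Size` is measured as total edge *cost*, not edge count, so that
low-confidence edges are penalized — consistent with probabilistic
parsimony. The default α = 0.25 favours parsimony while still
penalizing circuitous paths; α = 0 reduces to shortest-path union,
α = 1 to a pure Steiner-tree objective. No margin/slack parameter is
implemented.

### Approximate solver

Two candidates are built and the cheaper kept:

1. **SP-union** — union of minimum-cost `r→t` paths (optimal at α = 0);
2. **Steiner candidate** — metric closure over {root} ∪ terminals ∪
   required nodes (pairwise direction-respecting shortest-path costs,
   symmetrized by the cheaper direction), minimum spanning tree of the
   closure, expansion to the underlying paths, and removal of
   non-terminal leaves. This is the classical 2-approximation for the
   Steiner tree objective. Because PDI direction can make an expanded
   undirected tree miss root→terminal reachability in corner cases, the
   candidate is feasibility-repaired by adding SP-union paths for any
   unreachable terminal before comparison.

The winner is then pruned: connector nodes are removed greedily (in
lexicographic order, repeated to a fixed point) whenever removal keeps
all terminals reachable and does not increase `f`; finally the subgraph
is restricted to the union of its own minimum-cost root paths, which
guarantees that every connector lies on at least one terminal path and
can only decrease `f`. Required nodes ("manually added") join the
connectivity requirement but not the path term; excluded nodes are
deleted before solving; terminals left unreachable are dropped with a
warning rather than failing the query.

All tie-breaks — Dijkstra predecessor choice (fewest hops, then
smallest label; the hop ordering also keeps predecessor chains acyclic
across zero-cost root edges), metric-closure MST edge order, pruning
order — are lexicographic on node identifiers, so outputs are
deterministic and equivariant under node relabeling.

### Exact solver

The exact formulation has a binary `x_e` per edge, a binary `y_v` per
node, and per-terminal flows `f_{t,a} ∈ [0, 1]` over arcs (each PPI
contributes two arcs, each PDI one), with flow conservation routing one
unit from root to each terminal, `f ≤ x` coupling, and `x_e ≤ y_u,
x_e ≤ y_v`. The objective
`α Σ c_e x_e + (1−α) Σ_t Σ_a c_a f_{t,a}` equals `f(H)` at any optimum,
because each terminal's optimal flow follows a minimum-cost path inside
the selected subgraph. Flows are declared continuous: with `x` binary an
optimal extreme solution is integral per terminal; the implementation
verifies after solving that each terminal's flow cost equals its in-`H`
shortest-path cost and re-solves with binary flows if not (not observed
in practice). The backend is HiGHS through `scipy.optimize.milp`,
behind a formulation that any mixed-integer linear solver can run. The
default time limit is 1800 s; on hitting it the incumbent is returned
with `optimal=False` and a warning recommending the approximate solver.
A brute-force oracle (exhaustive edge-subset enumeration, guarded at 20
edges, lexicographic tie-break) provides independent verification.

### Other query modes

*General* (no anchors): the same metric-closure Steiner construction
over the terminal set; terminals in different components are solved per
component with a warning; the path term is 0 by convention. *Shortest
paths*: per anchor–terminal pair, the minimum-cost direction-respecting
path and its likelihood `exp(−cost)`; unreachable pairs are flagged,
not errors. *Local search*: the induced subgraph within a hop radius of
the terminals, direction ignored.

## Endpoint inference

**Transcription factors.** For each TF with at least one target in the
universe (all network nodes, not only PDI-annotated genes — the
conservative universe), the upper-tail hypergeometric probability of
the observed overlap between its targets and the terminals is computed
(`scipy.stats.hypergeom.sf`), adjusted by Benjamini–Hochberg
(statsmodels); TFs with `q ≤ fdr` (default 0.05) are enriched. Enriched
TFs become the terminals of the downstream anchored query, and
terminals covered by no enriched TF are eliminated as likely expression
noise. With no enriched TF the original terminals are kept, with a
warning.

**Anchors.** Scores are propagated by
`s ← (1−β)·prior + β·P s`, `P` the row-normalized (neighbor-mean)
undirected adjacency; isolated nodes keep their prior. β ∈ [0, 1)
makes the update a contraction; the fixed point solves
`(I − βP) s = (1−β)·prior`. Defaults: β = 0.8 (strong smoothing, usual
for propagation-based prioritization), tolerance 1e−6 on the maximum
absolute change, 1000 iterations maximum. The mean (row-normalized)
reading of "average scores of its neighbors" is implemented; symmetric
normalization is not. The top 100 non-terminal scorers are candidates;
100 propagations from random node sets of terminal size (drawn from all
non-terminal nodes) form the null; a candidate survives only if its
real score strictly exceeds its score in *every* null run (empirical
p ≤ 1/101). Null runs that happen to draw the candidate itself as a
seed are excluded from that candidate's comparison — a self-seeded run
scores the candidate near its prior of 1 and says nothing about the
terminals. Up to 3 survivors are reported greedily by descending score,
skipping candidates adjacent to an already-selected one (any edge kind,
either direction), so reported anchors are independent entry points.

## Confidence scoring

Evidence features are nonnegative counts per evidence type (e.g. assay
counts per experimental method, distinct publications). The model is
logistic: `P(true) = σ(b + w·x)`, fitted by damped Newton iterations on
the L2-penalized Bernoulli log-likelihood (penalty `λ/2·‖w‖²` on
coefficients only, default λ = 1e−4 to guarantee existence under
separation; tolerance 1e−8 on the gradient max-norm, 200 iterations).
Training data: curated positive pairs, plus negatives sampled uniformly
(seeded) from edges whose endpoint hop distance *after removing the
edge itself* is at least `min_distance` (default 3; disconnection
counts as infinite). The rationale: an edge that is the only short
route between its endpoints is topologically load-bearing and a poor
candidate for a spurious observation, so far-apart pairs are cleaner
negatives. Fitted scores lie strictly in (0, 1) and feed directly into
the network reader as confidences.

## Statistical report

Chance inclusion probabilities use a terminal-resampling null: the same
anchored query is re-run `n_random` (default 100) times with terminal
sets drawn uniformly without replacement from non-anchor nodes,
terminal count fixed and anchors held. Each original solution node is
reported with the fraction of null solutions containing it; anchors and
required nodes are part of every null query by construction and report
probability 1. Degree-matched sampling is available but off by default.
Edge-rewiring nulls are not implemented; the resampling null directly
answers "would this node appear for random terminals of the same
size?". Path likelihoods (product of edge confidences) accompany every
terminal path. The report is purely empirical; no analytical p-values.

## Synthetic data

The generators define the conditions under which the package is
validated. Backgrounds are Erdős–Rényi with expected mean degree as
given (a preferential-attachment option exists because propagation is
degree-sensitive); edge confidences uniform on (0.3, 0.7) — costs
around 0.7 ± 0.3 — with a configurable PDI fraction (default 0.1,
random orientation). Planted instances overwrite chains of fresh
connector nodes between anchors and terminals with confidence 0.99
edges (cost ≈ 0.01), a separation under which a correct solver should
recover planted routes essentially always; recovery is measured over
planted connector nodes. Evidence tables draw Poisson(1) feature counts
and Bernoulli labels from a stated logistic model. Every generator is a
pure function of its parameters and seed.

What the synthetic conditions do *not* emulate: the degree
distribution, clustering and confidence calibration of real
interactomes, correlated evidence across interactions, or biologically
structured terminal sets. Passing tests therefore demonstrate
algorithmic correctness under controlled conditions, not biological
performance on any particular organism's network.

## Problem sizes and numerical choices

Validation uses instance sizes at which independent oracles are exact:
solver cross-validation on ≤ 9-node/≤ 16-edge instances (30 draws)
against full subset enumeration; approximation-ratio measurement on 100
instances of ≤ 12 nodes against the ILP; hypergeometric agreement over
every (N ≤ 12, K, n, k); propagation against a dense linear solve at 50
nodes; recovery on 20 backgrounds of 500 nodes with 2 anchors, 5
terminals, 3-hop planted paths; scoring recovery at n = 5000 records.
Floating-point ties in solvers use a 1e−12 epsilon; objective
comparisons in tests use 1e−6 to 1e−9 absolute tolerances depending on
whether an ILP solve is involved.

## Known limitations

- The directed-Steiner corner of the approximate solver is handled by
  feasibility repair, not by a directed approximation guarantee; the
  2-approximation bound is with respect to the undirected construction
  and is verified empirically against the exact optimum.
- The ILP grows as O(|terminals| · |arcs|) flow variables; it is meant
  for queries with up to roughly 20 terminals, mirroring the advisory
  time limit and fallback to the approximation.
- Duplicate edge records collapse optimistically to the maximum
  confidence.
- Node identifiers are opaque case-sensitive strings; no gene-symbol /
  accession mapping is performed.
- The TSV network dialect cannot represent isolated nodes (the SIF
  dialect can).
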