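# Methods

## Model

An instance is a 6-tuple (S, G, ϕ, d, t, ℓ): rooted binary species and
gene trees, a mapping ϕ from gene leaves to species leaves (total on the
gene leaves, not necessarily injective or surjective), and non-negative
costs for duplication (d), transfer (t) and loss (ℓ); speciation is a
null event.  Trees are undated; branch lengths are accepted on input and
ignored.  A reconciliation mapping Φ places every gene vertex on a
species vertex, extending ϕ, such that Φ(g) is never a proper descendant
of a child's image and at least one child's image lies in the subtree of
Φ(g).  Each internal gene vertex then induces exactly one speciation,
duplication or transfer event, and each non-root vertex induces one loss
per species vertex it passes through on the way down from its parent's
association.  Temporal feasibility of transfers is *not* checked (the
time-consistent variant of the problem is NP-complete and out of scope
here), and dated trees are not supported.

## Dynamic program and reconciliation graph

`compute_dp` fills, for every pair (g, s):

* `event_cost(g,s)` — cheapest reconciliation of g's subtree with an
  event at s, via the standard case analysis (speciation across the two
  child subtrees of s, duplication at s, transfer keeping one child at s
  and sending the other to the cheapest non-ancestrally-related vertex);
* `descend(g,s) = min(event_cost(g,s), ℓ + min over children of descend)` —
  entry at-or-below s with losses charged per vertex passed through;
* `outside(g,s)` — min of `event_cost(g, ŝ)` over ŝ incomparable to s
  (computed by a plain O(n²) scan per gene vertex; the contract is the
  value, not the complexity).

The optimum is `min_s event_cost(root(G), s)`; no losses are charged
above the gene root.  Infinite entries are `math.inf`, which propagates
correctly through min/+ arithmetic.

`build_recon_graph` backtracks **all** argmin choices into a DAG with one
mapping node per (g, s) pair used and one event node per achieving event
tuple; loss nodes insert pass-through mapping nodes.  Two entry modes
exist for a mapping node: *event* entry (graph sources and transfer
recipients, which must place their event exactly at s — a transfer
recipient incurs no recipient-side losses, matching the event tuple
(𝕋,(g,s),{(g′,s),(g″,ŝ)})) and *descend* entry (speciation/duplication
children, transfer donors and loss children, which may pass through).
With ℓ > 0 one can show an optimal source or transfer recipient never has
a loss child at its budget, so sharing one node per (g, s) is sound.
With ℓ = 0 the shared representation can become ambiguous (a loss chain
below a recipient would duplicate an MPR already represented by a deeper
recipient); `build_recon_graph` detects exactly that situation and
refuses with a clear error rather than over- or under-counting.  On
randomized ℓ=0 instances where no ambiguity arises the graph remains
exactly the MPR set (tested against the oracle).

## Subgraph statistics

A subgraph is fully described by its event-node set and its sources;
mapping nodes and adjacency are derived (an event's mapping children are
its association pairs).  Counting uses the usual two-pass scheme: `below`
(completions beneath a node) in reverse topological order, `above`
(completions above) forward, and `c(e) = above(e) · Π below(children)`.
All counts are exact Python integers — MPR counts beyond 10¹² occur
already at 50-leaf trees.

* support(e) = c(e)/T; the cluster summary σ is the **unweighted mean over
  distinct non-ℂ event nodes**.  ℂ (contemporaneous leaf) events occur in
  every MPR of every subgraph, so including them would add a constant
  offset to σ and nothing to any distance; they are therefore excluded
  from σ, μ and median weights.  A leaf-only space (no non-ℂ events) has
  σ defined as 1.  A frequency-weighted σ would be a defensible
  alternative; distinct-node averaging was chosen and is applied
  consistently everywhere.
* μ is the mean symmetric distance |E(R₁)⊕E(R₂)| over **unordered
  distinct** pairs, computed by the per-event decomposition
  Σ_e c(e)(T−c(e)) / (T(T−1)/2): event e lands in exactly one member of
  a pair for exactly c(e)(T−c(e)) pairs.  Singletons have μ = 0.  This
  avoids the much costlier full distance-distribution recursion; distance
  *histograms* are produced by enumeration for small T and by seeded
  uniform sampling otherwise.
* The median traversal maximizes Σ_{e∈E(R), non-ℂ} (c(e) − T/2) by a
  reverse-topological best-choice sweep using integer weights 2c(e) − T,
  so it is exact.
* Uniform sampling draws the source with probability below/T and each
  event child proportionally to its completion count, giving i.i.d.
  uniform MPRs.

Ties everywhere (median choices, linkage argmax) are broken by a fixed
total order on nodes — (gene preorder index, species preorder index,
event rank 𝕊<𝔻<𝕋<𝕃<ℂ, associations) — so all outputs are reproducible
bit-for-bit; child order in the input trees does not affect any reported
statistic.

## Clustering

Level-0 subtraversals are the graph sources, one cluster seed per
source.  Each expansion round advances every expandable frontier mapping
node by one chosen event child (cartesian product over the frontier);
frontier nodes with only ℂ children close.  The smallest level L with at
least the requested number of subtraversals is used (default request 25,
cap 200 with either refusal or fallback to level L−1).  Each
subtraversal's downward closure is an initial cluster; because no
alternative event child of a prefix node is reachable from its own
frontier, the initial clusters partition MPR space — Σ|Cᵢ| = T, a
property the tests verify by enumeration at every feasible level.

Merging is greedy to k = 1 even when every candidate merge worsens the
objective; the recorded history lets users pick k afterwards from the
improvement (objective at k vs. at 1) and local improvement
(WASlocal_k = WAS({C_a,C_b}) / WAS({C_ab}), WADlocal_k inverted) scores.
Candidate merges recompute statistics on the union subgraph rather than
combining part statistics: a union can contain MPRs absent from both
parts (mixed choices), so |C_ab| may exceed |C_a| + |C_b| and no
algebraic shortcut is exact.  Candidate evaluations are cached per
cluster-id pair and only pairs touching the last merge are recomputed.
The linkage compares whole-clustering WAS/WAD values as exact rationals
(`fractions.Fraction` over exact integer counts), eliminating
floating-point ties; floats appear only in serialized output.  Division
by zero in improvement ratios (e.g. WAD of an all-singleton clustering)
yields an explicit `inf`.  An optional wall-clock timeout aborts with a
partial history and a distinct CLI exit status.

The WAD linkage minimizes the candidate whole-clustering WAD (not only
the local pair's): since merged sizes change the weight normalization,
the two are not equivalent, and the whole-clustering delta is the one
that matches the gradient-descent reading of the objective.

## Synthetic data

The generator draws uniform random rooted binary topologies by recursive
random splits of the leaf set, maps gene leaves to species leaves either
bijectively or i.i.d. with replacement (the default, which produces the
duplication/transfer-rich discordance the clustering machinery needs),
and draws costs from a grid whose defaults are (1,1,1), (2,3,1) and
(1,4,1) — the unit scheme plus the two cost settings most used for
prokaryotic gene-family analyses.  Identical seeds give identical
instances.  The generator emulates topological discordance only: it does
not simulate a generative DTL process along the species tree, branch
lengths, or rate heterogeneity, so passing tests demonstrate algorithmic
correctness on discordant tree pairs, not calibration against any
biological event-rate regime.

Oracle-backed tests run at desk scale: trees of ≤ 6 leaves for exhaustive
mapping enumeration (hundreds of instances in seconds) and MPR spaces of
2–500 traversals for enumeration-based statistics checks.  The scale
smoke test uses a 50×50-leaf instance (≈ 3·10¹⁰ MPRs, clustered from 64
initial clusters in well under a minute); the acceptance script's
clustering demonstration uses a 20×20-leaf instance.

## Known limitations

* Loss cost exactly 0 combined with transfers can be refused (see above);
  all standard cost settings have ℓ > 0.
* No dated/timed variant, no temporal-feasibility filtering, no path
  distance metric (the symmetric metric is the one implemented), and no
  automatic choice of k (silhouette/gap-style selection is left to the
  user via the recorded history).
* Cluster membership queries are supported only for traversals produced
  by this package (subgraph containment of an event set), not for
  arbitrary externally produced reconciliations.
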