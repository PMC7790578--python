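# Methods

## Scope and model

`netpharm` implements the inference chain of a two-herb network-pharmacology
study as composable, deterministic operations over plain data structures:
compound tables, compound→gene target maps, gene sets, an undirected simple
PPI graph (a `networkx.Graph` over gene symbols), a per-node centrality
table, and an enrichment table. The chain makes no mechanistic claims: it is
descriptive network triage — which targets of a compound collection sit in
densely interconnected, disease-overlapping neighbourhoods, and which
annotation terms those targets over-represent.

## ADME screen

A compound is *active* when `ob >= ob_min` and `dl >= dl_min`, both
inclusive; defaults 30 (%) and 0.18 (dimensionless). Inclusivity matters:
compound tables routinely carry entries exactly at the drug-likeness
boundary, and an exclusive rule would silently drop them. Compounds flagged
`manual_add` model the expert-judgement practice of carrying
pharmacologically canonical constituents that fail the screen; they pass
only when `include_manual` is requested and, by convention, contribute no
targets downstream.

## Gene identity and set algebra

Gene identity is the uppercased, whitespace-trimmed HGNC-style symbol
string; no alias resolution is attempted, so two spellings of the same gene
are different genes. Disease gene lists are accepted verbatim (no scoring
threshold). Every two-set report asserts the inclusion–exclusion identity
`|A| + |B| = |A∪B| + |A∩B|` at construction, so an inconsistent report
cannot be instantiated. `intersection_size_from_counts` inverts the same
identity for published size triples and rejects unrealisable ones.

## Network construction

The bipartite compound–target network restricts the target map to
(given compounds) × (given genes); compounds or genes left without edges are
dropped, which is how target-less compounds vanish from such networks.

PPI ingest accepts the STRING export dialect (`protein1 protein2
combined_score`, score an integer in [0, 1000]). Both orientations collapse
to one canonical edge, self-loops are dropped, and edges below `score_min`
(default 400, STRING's "medium confidence"; the appropriate cut is
data-dependent, hence a flag) are discarded. Scores are used *only* at
ingest: all centrality work is unweighted, matching the integer degrees such
studies tabulate. "Removal of discrete points" is interpreted as: restrict
to the supplied gene set (e.g. the drug∩disease overlap), then delete
degree-0 nodes. The handshake lemma is asserted after every ingest.

## Centrality measures

For an undirected simple graph, per node `v`:

- **DC** `= |N(v)|`, the raw integer degree.
- **BC** `= Σ_{ {s,t}, s≠v≠t } σ_st(v)/σ_st` over *unordered* pairs,
  unnormalised (Brandes accumulation; pairs in different components
  contribute 0). The unordered/unnormalised convention is recorded here
  because tools differ silently on it.
- **CC** `= (n_c − 1) / Σ_{u∈comp(v)} d(v,u)` within `v`'s component of
  size `n_c`; isolated nodes score 0. No cross-component correction is
  applied because the analysed graph is cleaned to its connected core first.
- **EC**: the principal eigenvector of the adjacency matrix, non-negative,
  unit Euclidean norm over all nodes. Computed by power iteration on
  `A + I` — the shift leaves eigenvectors unchanged but makes the dominant
  eigenvalue strictly largest in modulus, so bipartite-structured graphs do
  not oscillate. Defaults: uniform start, `tol = 1e-10` on the max absolute
  change of the normalised iterate, `max_iter = 10000`. Non-convergence
  raises; there is no silent partial result.
- **LAC** `= (1/|N(v)|) Σ_{w∈N(v)} deg_{G[N(v)]}(w)`: the mean degree of
  `v`'s neighbours inside the neighbourhood-induced subgraph; 0 for
  degree-0 nodes.
- **NC** `= Σ_{w∈N(v)} ECC(v,w)` with edge clustering coefficient
  `ECC(u,w) = z(u,w) / min(deg(u)−1, deg(w)−1)`, `z` the number of triangles
  on the edge. When the denominator is 0 (an endpoint of degree 1) the ECC
  is 0 by default; the alternative convention of 1 exists in the literature
  and is available via `degenerate_value=1.0`.

DC, BC and CC are delegated to networkx with the conventions pinned
(`normalized=False`, `wf_improved=False`); EC, LAC, NC, MCC and the
consensus filter are implemented here. The test suite checks *every*
measure, delegated or not, against naive brute-force recomputation
(exhaustive simple-path enumeration for BC/CC, dense eigendecomposition
residuals for EC, literal subgraph recounting for LAC/NC, subset-enumeration
maximal cliques for MCC) on every graph with at most 7 nodes (the full
1,252-graph atlas) and on seeded random 8-node graphs across edge densities
0.1–0.9. Exhaustiveness stops at 7 nodes because enumerating the 12,346
non-isomorphic 8-node graphs requires nauty-style generation; random
sampling covers n = 8.

## Median-consensus hub selection

Per-metric medians are computed over all table rows (even counts: mean of
the two middle values), unless precomputed medians — e.g. published ones
from a larger network — are supplied. A node is retained only if it meets
the median on *all six* metrics; `rule="inclusive"` (`>=`, the default)
versus `"strict"` (`>`) is exposed because "above the median" is ambiguous
in prose descriptions of the method; on the packaged hub table both rules
retain all 13 rows, so the default is benign. Retained nodes are ordered by
degree descending, ties alphabetical.

## MCC ranking

`MCC(v) = Σ (|C|−1)!` over maximal cliques `C ∋ v`, exact integers, cliques
enumerated by Bron–Kerbosch with pivoting. Singleton "cliques" (isolated
nodes) contribute 0. Because maximal-clique counts can explode on
pathological graphs, enumeration beyond a configurable cap (default 10⁶)
raises instead of running unbounded. Top-k ties are broken by MCC
descending, then degree descending, then name ascending; the rule is
recorded on the ranking object since published analyses never state one.

## Over-representation analysis

For query size `n` (after restriction to the universe), term size `K`,
universe size `N` and overlap `k`, the p-value is the upper tail
`P(X ≥ k)` of the hypergeometric distribution, computed through the
survival function for numerical stability. Terms with `k = 0` are not
tested (matching common tools; this also defines the BH family as the
tested terms only). q-values are Benjamini–Hochberg step-up values;
"q-value" in tool output conventionally means BH FDR and that is what is
implemented. Significance requires `p ≤ p_cut` and `q ≤ q_cut` (defaults
0.05/0.05). The universe defaults to the union of all term genes — the
common tool default — but it changes every p-value, so it is overridable
and recorded in output.

## Synthetic data generators

Each generator is a pure function of `SimConfig` (seeded numpy Generator
substreams per generator, so outputs are bitwise-reproducible and
independent of call order) and returns a manifest whose every quantity is
recoverable by running the corresponding pipeline stage — the closed-loop
property the tests rely on. Defaults mirror the scale of a real two-herb
study: 26 + 13 compounds; 6 + 10 of them carrying targets (16 of 39); herb
target sets of 13 and 41 genes sharing exactly 7 (union 47); a 20,000-gene
universe; a 7,153-gene disease list planted to contain exactly 44 drug
targets; a 39-node PPI; 50 annotation terms of 10–60 genes with one term
planted to hold 10 query genes.

Distribution choices (real studies are database pulls, not draws, so these
are modelling choices): OB and DL are uniform on [0, 100] and [0, 1], which
puts the default screen's expected pass rate at 0.70 × 0.82 ≈ 0.574; herb
pool genes are assigned round-robin to mapped compounds (so planted set
sizes are exact, not in expectation) plus Poisson(3) extra draws per
compound; the PPI backbone is Barabási–Albert preferential attachment
(attachment 5 reproduces the edge density of a ~39-node/186-edge network;
attachment 1 yields a tree, useful as a triangle-free control), with a
planted clique fully wired over randomly chosen nodes and integer edge
scores uniform on [400, 999].

What the generators do *not* emulate: correlated ADME descriptors, target
promiscuity structure (hub compounds), literature-biased disease lists,
STRING's score-dependent topology, and GO's term nesting/redundancy.
Passing closed-loop tests therefore certifies the *pipeline arithmetic*,
not robustness to real-database artefacts.

## Stochastic benchmark design

- **Planted-clique recovery.** A K6 planted uniformly at random into a
  40-node attachment-2 backbone tops the MCC ranking unless a background
  hub happens to be adjacent to ≥ 5 clique members, completing a competing
  6-clique; exploration across 200 seeds shows this occurs in ~1–2% of
  placements regardless of backbone sparsity. Recovery is therefore
  asserted at ≥ 90% over 50 seeds rather than universally.
- **ORA calibration.** Power: with universe 2,000, term size 40, query 15
  with 10 planted hits, the planted term's p-value is astronomically small,
  so ≥ 95% recovery at `q ≤ 0.05` over 200 replicates is expected to be
  met with margin (observed: 100%). Null: hypergeometric p-values are
  super-uniform (discrete), so the per-term rate of `p ≤ 0.05` under random
  queries is bounded by 0.05 in expectation (observed ≈ 0.017), and BH
  rejections per replicate stay near zero.

Problem sizes throughout the test suite (atlas ≤ 7 nodes, 200 random
8-node graphs, 50 clique seeds, 2 × 200 ORA replicates, exhaustive
hypergeometric checks for N ≤ 15) were chosen as the smallest scales at
which the checked properties are non-trivial; the whole suite runs in well
under a minute.

## Known limitations

- No alias/ID mapping: symbol-string identity only.
- The PPI is unweighted past ingest; confidence-weighted centralities are
  out of scope.
- ORA ignores term ancestry and overlap (no GO DAG traversal or
  redundancy trimming), and tests only terms with ≥ 1 hit.
- Published end-to-end counts that depend on unversioned database
  snapshots (disease list sizes, PPI edge counts, pathway tallies) are
  represented by synthetic closed loops, not reproduced from live sources.
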