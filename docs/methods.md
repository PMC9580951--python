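# Methods

## Scope and model

The package analyses undirected protein-protein interaction graphs with a
distinguished protein family. Three graphs are derived from one merged
interaction corpus: the global network (simple, self-loops dropped), the
family neighbourhood network (induced subgraph on the family and its direct
interactors, *including* interactor-interactor edges — the neighbourhood's
own wiring is part of the object of study), and the intra-family network
(weighted by evidence counts, self-loops kept as a proxy for
homo-oligomerization). All statistics treat edges as unweighted except where
noted; weights and self-loops are bookkeeping for the intra-family view and
are excluded from density and clique computations.

## Corpus semantics

Gene symbols are upper-cased and whitespace-stripped; no alias resolution is
attempted, because symbol-to-symbol mapping without an external service is
not deterministic. Each unordered pair is keyed canonically
(lexicographically ordered). Merging unions corpora over canonical pairs:
the evidence count of a merged pair is the total evidence carried by all
contributing records (each raw parsed row carries one unit, so duplicates
within and across sources accumulate — duplicate rows are treated as
separate evidence items, matching the publications-and-techniques weighting
of the intra-family edges), and the maximum confidence seen is retained —
when sources disagree on a score, the more optimistic one wins, an
explicit design choice. No confidence filtering is applied by default;
filtering at a threshold (conventionally 0.63 for HIPPIE-style scores) is an
opt-in, and the ingest report always states how many scored records fall
below the threshold, with unscored records counted separately. Malformed
rows are skipped and counted rather than aborting, since large curated dumps
routinely contain irregular lines.

## Graph statistics and conventions

Several quantities admit multiple conventions; the ones implemented are:

- **Density** `2|E| / (|V|(|V|−1))` with self-loops excluded from E.
- **Compactness**: with `k = ln E / ln V`, a graph is "dense" when
  `1 < k < 2`, otherwise "sparse"; degenerate graphs (V < 2 or E = 0) are
  sparse.
- **Radius/diameter** are reported for the largest connected component, and
  the average shortest path is taken over connected pairs only, so the
  values stay finite on fragmented networks.
- **Average clustering** is the mean local coefficient over nodes of degree
  ≥ 2. The coefficient of a degree-0/1 node is undefined (0/0); counting such
  nodes as zero is available behind a flag but not the default.
- **Betweenness** is Brandes' accumulation, unnormalized, endpoints
  excluded, each unordered pair counted once (the two-endpoint accumulation
  is halved).
- **Closeness** is `1 / Σ d(u, v)` where an unreachable pair contributes
  distance |V|. This legacy convention keeps closeness defined and
  order-preserving on disconnected graphs; its absolute values are small
  (≈ 1/(|V| · unreachable count)) by construction.
- **Eccentricity** is computed within a node's own component.
- **Eigenvector centrality** is the principal eigenvector of the adjacency
  matrix, obtained by power iteration on (A + I) — the shift leaves the
  eigenvectors unchanged while preventing sign alternation on bipartite
  components — started from a uniform positive vector, iterated to a
  max-norm change below 1e-10, and max-normalized so the top node scores 1.
- **Core numbers** come from bucket-based minimum-degree peeling
  (Batagelj–Zaversnik), O(V + E).
- **Hubs** are nodes with degree *strictly* above the arithmetic mean
  degree. Family association is tested on the 2×2 (family × hub) table with
  the Pearson chi-square, no continuity correction by default (Yates is a
  flag); a table with an empty margin is reported as degenerate rather than
  producing a NaN. The k-core group-threshold chi-square takes its threshold
  as a required argument: no principled default exists, so none is supplied.

## Power-law fit

The degree tail is fitted by discrete maximum likelihood:
`P(x) = x^(−α) / ζ(α, x_min)` for `x ≥ x_min`, with α maximized per
candidate `x_min` (bounded scalar minimization of the negative
log-likelihood over α ∈ (1.01, 8)) and `x_min` chosen to minimize the
Kolmogorov–Smirnov distance between the empirical and fitted tail CDFs.
Both CDFs are step functions on the same integer support, so the KS supremum
is evaluated at the support points only. The default p-value is the analytic
Kolmogorov distribution evaluated at `√n_tail · KS`; because α and `x_min`
are estimated from the same data this p-value is conservative (biased
upward), which is acceptable for its role here — *failing to reject* the
power-law hypothesis on genuinely scale-free data. A Clauset-style
semi-parametric bootstrap (refitting on synthetic samples drawn from the
fitted tail and the empirical body) is available behind a flag, default 100
replicates. The fit requires at least 10 distinct degree values; a constant
degree sequence is a typed fit-undefined error.

## Cliques

Maximal cliques are enumerated by Bron–Kerbosch with max-intersection
pivoting, with the outer recursion driven by a degeneracy order. All cliques
of size ≥ m are obtained by expanding subsets of the maximal cliques with
deduplication — valid because every clique lies inside a maximal clique of
at least its size. Output is fully deterministic: members sorted within each
clique, cliques sorted lexicographically.

The packaged curated clique table for the bromodomain family is used as a
fixed point: rebuilding the intra-family graph as the union of within-clique
edges and re-enumerating returns exactly the 39 curated maximal cliques and
273 total cliques of size ≥ 3. The reconstruction omits any intra-family
edge that is part of no triangle, but such edges cannot contribute to any
clique of size ≥ 3, so the size-≥3 clique complement is preserved exactly —
this equivalence argument is what makes the fixed-point test sound, and it
is asserted (not assumed) in the test suite.

## Modified similarity

`S_ij(s) = |N_s(i) ∩ N_s(j)| / |N_s(i) ∪ N_s(j)|` with `N_s(x)` the set of
nodes at shortest-path distance *exactly* s (a ring, not a ball) and the
focal pair removed from both sets. Three design points deserve note:

- The denominator is the size of the **union** of the two distinct-neighbour
  sets, not the sum of the set sizes. A sum denominator is algebraically
  capped at 0.5 (`|A∩B| ≤ min(|A|,|B|) ≤ (|A|+|B|)/2`) and therefore cannot
  express near-identical neighbourhoods; the capped variant is retained as
  `denominator="sum"` for comparison, and the cap is asserted in the tests.
- "At distance 2 and 3" is read as exact distance, so the s = 2 score is not
  contaminated by direct neighbours.
- Pairs whose union is empty score 0 by convention, keeping the matrix
  total; the diagonal is 1 whenever the node has a non-empty ring.

Hierarchical leaf ordering for heatmap export uses average-linkage
agglomeration on (max − S) for similarities or the raw distances (with
unreachable sentinels mapped to one step beyond the largest finite
distance), with labels pre-sorted so ties break lexicographically.

## Statistical tests

- **Wilcoxon rank-sum**, two-sided: exact by full enumeration of rank
  assignments when the pooled sample has ≤ 12 observations and no ties
  (two-sided p = probability of a rank sum at least as far from its null
  mean); otherwise the normal approximation with mid-ranks, tie-corrected
  variance and a continuity correction of 1/2. The 12-observation switch
  keeps exact enumeration at C(12,6) = 924 assignments, instantaneous.
- **Chi-square** on 2×2 tables: Pearson statistic, 1 d.f., no continuity
  correction by default.
- **Hypergeometric upper tail** P(X ≥ k): PMF terms accumulated in log space
  via log-gamma, stable for populations of tens of thousands; k = 0 returns
  exactly 1.
- **Benjamini–Hochberg**: step-up with monotonicity enforcement, q-values
  clipped to [0, 1], input order preserved.

All tests return finite statistics or raise typed errors; none emits NaN.

## Enrichment

The default background is N = 23,467 genes — the protein-coding universe
used by common hypergeometric-enrichment tools, and the value consistent
with published per-set membership p-values at the family's signature size
(e.g. K = 32, n = 42, k = 1 → p = 0.056). It is always overridable, and a
GMT parsed without a declared background defaults to the number of distinct
symbols in the file. The enrichment signature for interactor-level analysis
is the set of *non-family* nodes of the family neighbourhood network.
Involvement profiles count, per family protein and selected pathway, the
distinct direct non-family interactors belonging to the pathway (an
interactor in several pathways counts once per pathway), then row-normalize
across the selected pathways; zero rows are flagged, not dropped. Pathway
sub-networks are bipartite by construction: family nodes with ≥ 1 pathway
interactor, those interactors, and only the family-to-interactor edges.

## Synthetic data

The generator emulates the statistical shape of curated human PPI corpora,
not any specific corpus:

- **Global network**: preferential attachment (complete seed on m + 1
  nodes, each newcomer attaching to m distinct degree-proportional targets),
  giving the heavy-tailed degree distribution that the power-law fit is
  meant to detect. Default n = 2,000 nodes, m = 3; n = 10,000 is used where
  exponent recovery is the point.
- **Planted family**: 42 members by default (the size of the bromodomain
  family), chosen uniformly after growth, then wired with extra uniform
  random edges until each reaches 3× the pre-boost mean degree. Planting
  after growth decouples the hub effect size from the attachment exponent.
- **Gene sets**: 50 sets (the size of the standard Hallmark collection) with
  sizes uniform in [32, 200] (the Hallmark size range), one designated set
  drawing 80% of its members from the signature.
- Labels use fixed prefixes (`FAM…`, `PRT…`); HIPPIE-dialect confidence
  scores are a CRC32 hash of the canonical pair mapped to [0, 1], so files
  are byte-stable without an extra seed. All generators are pure functions
  of (spec, seed).

What the synthetic data does *not* emulate: literature bias (degree
correlated with publication count), experimental false-positive structure,
inter-database redundancy, or the community structure of real interactomes.
Passing the planted-recovery tests therefore shows the estimators detect the
effects they target at realistic sizes — not that real corpora satisfy the
generative assumptions.

## Problem sizes and numerical choices

Oracle-equivalence checks run on random graphs of up to 60 nodes, where
exhaustive and reference computations are exact and fast; recovery checks
use 2,000-node networks over 20 seeds (hub and enrichment planting) and
10,000-node samples (exponent recovery, ±0.1 tolerance), sizes at which the
estimators' sampling noise is well inside the asserted bands. Power
iteration tolerance is 1e-10 in max norm; the power-law α search is bounded
to (1.01, 8); Wilcoxon calibration uses 2,000 null replicates at n = 50 per
group. Degenerate inputs are first-class: empty corpora build empty
networks, single-node networks report undefined distances as such, constant
degree sequences and empty contingency margins raise typed errors.

## Known limitations

- No identifier mapping: symbol collisions or aliases in the input are the
  caller's responsibility.
- The closeness penalty convention makes absolute closeness values
  incomparable across graphs of different size (rank order is preserved).
- The analytic KS p-value for the power-law fit is conservative; use the
  bootstrap flag when rejection decisions matter.
- Total-clique enumeration is exponential in the largest clique size; it is
  intended for small dense intra-family graphs, not the global network.
- The pipeline holds the full graph in memory; it targets corpora up to a
  few hundred thousand edges, not full multi-species interactome unions.
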