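# brdnet

Topology, clique, similarity and pathway-enrichment analysis of
protein-protein interaction networks (PPINs) centred on a protein family —
built for the human bromodomain-containing (BRD) proteins, the 42 genes whose
products read acetyl-lysine marks and scaffold chromatin-associated
complexes, but usable for any family of gene symbols.

## What it computes

Given curated physical-interaction tables (BioGRID TAB-style, HIPPIE-style,
or plain two-column TSV), the package builds three undirected graphs: the
**global PPIN** over all proteins, the **family PPIN** induced on the family
plus its direct interactors (interactor–interactor edges included), and the
**intra-family PPIN**, weighted by evidence counts and keeping self-loops
(homo-dimerization potential). On these it computes:

- **Whole-graph topology**: density `2|E| / (|V|(|V|−1))`, radius/diameter on
  the largest component, average shortest path over connected pairs, mean
  local clustering, component count, and a compactness class from the
  `E ≃ V^k` rule (dense when `1 < k < 2`).
- **Per-node metrics**: degree, unnormalized Brandes betweenness, closeness
  `1/Σd` with unreachable pairs penalized at distance `|V|`, eccentricity,
  max-normalized eigenvector centrality, local clustering, and k-core number
  by minimum-degree peeling. Hubs are nodes with degree strictly above the
  mean; family-vs-rest hub association is tested by Pearson chi-square, and
  metric distributions are compared by the two-sided Wilcoxon rank-sum test.
- **Scale-freeness**: discrete maximum-likelihood power-law fit
  `P(x) ∝ x^(−α)`, with `x_min` chosen by minimal Kolmogorov–Smirnov distance
  and a KS p-value for the fitted tail.
- **Complex prediction**: maximal cliques (Bron–Kerbosch with pivoting over a
  degeneracy order) and total clique counts at a minimum size of 3.
- **Functional similarity**: family distance matrices over the global graph,
  and the *modified similarity* between family members i, j at exact
  shortest-path radius s ∈ {1, 2, 3}:

  ```
  S_ij(s) = |N_s(i) ∩ N_s(j)| / |N_s(i) ∪ N_s(j)|
  ```

  where `N_s(x)` is the set of nodes at distance exactly s from x, with i and
  j excluded. At s = 1 this is the classic neighbour-set Jaccard similarity.
- **Gene-set enrichment**: upper-tail hypergeometric p-values for a signature
  against a GMT collection (default background N = 23,467),
  Benjamini–Hochberg FDR, top-pathway selection, per-family-protein pathway
  involvement profiles, and bipartite pathway sub-networks.

Every graph and statistical algorithm is implemented natively; networkx,
numpy.linalg and statsmodels appear only as independent oracles in the test
suite. A synthetic-data module generates the full input bundle — a
preferential-attachment network with a planted high-degree family,
dialect-faithful interaction tables, and gene-set collections with planted
enrichment — so the whole pipeline is testable without downloads.

## Worked example

The packaged curated maximal-clique table for the BRD family (39 cliques over
30 proteins) doubles as a fixed-point check of the clique machinery:

```python
from brdnet.datasets import load_brd_cliques
from brdnet.cliques import reconstruct_from_cliques, maximal_cliques, enumerate_cliques
from brdnet.network_core import summarize_topology

cliques = load_brd_cliques()
net = reconstruct_from_cliques(cliques)          # union of within-clique edges
topo = summarize_topology(net)
print(f"nodes={topo.n_nodes} edges={topo.n_edges} density={topo.density:.3f} "
      f"class={topo.compactness_class}")
print(f"maximal cliques (>=3): {len(maximal_cliques(net, 3))}")
print(f"all cliques   (>=3): {len(enumerate_cliques(net, 3))}")
```

prints

```
nodes=30 edges=110 density=0.253 class=dense
maximal cliques (>=3): 39
all cliques   (>=3): 273
```

i.e. re-enumeration recovers exactly the 39 curated complexes, and the graph
carries 273 complete subgraphs of size ≥ 3 in total.

An end-to-end run on synthetic data:

```sh
brdnet simulate --n 1000 --family-size 42 --boost 3 --seed 7 --out-dir sim
brdnet run --config config.yaml        # pointing at the sim/ bundle
```

The resulting `report.json` (plus one TSV per table) includes, for this seed:
a global network of 1,000 nodes and 3,526 edges (density 0.007, diameter 6,
mean shortest path 3.40); a power-law fit α = 2.59 at x_min = 4 with KS
p = 0.23 (the degree distribution is consistent with a scale-free network); a
hub chi-square p ≈ 4.5e−31 and degree Wilcoxon p ≈ 8.0e−25 (the planted
family is correctly detected as hub-enriched); mean off-diagonal modified
similarity rising from 0.011 (s = 1) to 0.115 (s = 2) and 0.451 (s = 3),
reproducing the qualitative jump in family similarity when indirect
neighbours are considered; and the planted gene set ranked first at
FDR < 0.05.

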