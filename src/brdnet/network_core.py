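"""Graph container and native topological statistics for PPI networks.

This module holds the analysis core: an adjacency-set :class:`Network`
container, builders for the three networks of interest (the global PPIN, the
family neighbourhood sub-network, and the weighted intra-family network with
self-loops), whole-graph topology summaries, per-node centrality and k-core
metrics, hub classification with a family-vs-rest chi-square, and a discrete
power-law fit of the degree distribution with a Kolmogorov-Smirnov tail test.

All graph algorithms are implemented here from first principles (BFS,
Brandes' betweenness accumulation, bucket-based k-core peeling, shifted power
iteration for eigenvector centrality, maximum-likelihood power-law fitting
with KS model selection); third-party graph libraries are used only as
independent oracles in the test suite.

Conventions, chosen to match the behaviour of classic PPIN analysis tooling:

* betweenness is the unnormalized count of dependent shortest-path pairs,
  endpoints excluded, each unordered pair counted once;
* closeness is ``1 / sum of distances`` where an unreachable pair contributes
  distance ``|V|`` (legacy all-graph convention, meaningful on disconnected
  networks);
* eccentricity is computed within a node's own connected component; radius
  and diameter are reported for the largest component;
* eigenvector centrality is max-normalized so the top node scores 1;
* hub = node with degree strictly above the network mean degree.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .exceptions import DegenerateTableError, FitUndefinedError
from .interaction_io import InteractionCorpus, canonical_pair
from . import stats as _stats

logger = logging.getLogger(__name__)

UNREACHABLE = -1  # sentinel for distances between disconnected nodes


class Network:
    """Simple undirected graph over gene symbols.

    Parallel edges are never stored. Self-loops are kept in a separate set
    and are only allowed when ``simple=False``. Optional per-edge weights
    (evidence counts) are stored against the canonical pair.
    """

    def __init__(self, simple: bool = True):
        self.simple = simple
        self._adj: dict[str, set[str]] = {}
        self.self_loops: set[str] = set()
        self.weights: dict[tuple[str, str], float] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, node: str) -> None:
        self._adj.setdefault(node, set())

    def add_edge(self, a: str, b: str, weight: Optional[float] = None) -> None:
        if a == b:
            if self.simple:
                raise ValueError(f"self-loop {a!r} not allowed in a simple graph")
            self.add_node(a)
            self.self_loops.add(a)
            if weight is not None:
                self.weights[(a, a)] = weight
            return
        self.add_node(a)
        self.add_node(b)
        self._adj[a].add(b)
        self._adj[b].add(a)
        if weight is not None:
            self.weights[canonical_pair(a, b)] = weight

    # -- inspection -------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        """Edge count excluding self-loops."""
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    @property
    def n_self_loops(self) -> int:
        return len(self.self_loops)

    def edges(self) -> list[tuple[str, str]]:
        """Canonical non-loop edges, sorted for deterministic output."""
        out = []
        for a, nbrs in self._adj.items():
            for b in nbrs:
                if a < b:
                    out.append((a, b))
        return sorted(out)

    def neighbors(self, node: str) -> set[str]:
        return self._adj[node]

    def has_node(self, node: str) -> bool:
        return node in self._adj

    def has_edge(self, a: str, b: str) -> bool:
        if a == b:
            return a in self.self_loops
        return b in self._adj.get(a, ())

    def degree(self, node: str) -> int:
        """Degree; a self-loop contributes 2, the handshake convention."""
        return len(self._adj[node]) + (2 if node in self.self_loops else 0)

    def degrees(self) -> dict[str, int]:
        return {n: self.degree(n) for n in self._adj}

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        """Induced subgraph on ``nodes`` (weights and self-loops carried over)."""
        keep = set(nodes) & set(self._adj)
        sub = Network(simple=self.simple)
        for n in keep:
            sub.add_node(n)
            if n in self.self_loops:
                sub.self_loops.add(n)
                if (n, n) in self.weights:
                    sub.weights[(n, n)] = self.weights[(n, n)]
        for a, b in self.edges():
            if a in keep and b in keep:
                sub.add_edge(a, b, self.weights.get((a, b)))
        return sub

    def audit(self) -> None:
        """Verify adjacency symmetry and loop bookkeeping; raises on corruption."""
        for a, nbrs in self._adj.items():
            for b in nbrs:
                if a not in self._adj.get(b, ()):
                    raise AssertionError(f"asymmetric adjacency {a!r}->{b!r}")
                if a == b:
                    raise AssertionError(f"self-loop stored in adjacency for {a!r}")
        if self.simple and self.self_loops:
            raise AssertionError("simple graph carries self-loops")
        missing = self.self_loops - set(self._adj)
        if missing:
            raise AssertionError(f"self-loops on unknown nodes {missing}")

    def components(self) -> list[set[str]]:
        """Connected components, largest first (ties broken by smallest label)."""
        seen: set[str] = set()
        comps: list[set[str]] = []
        for start in self.nodes:
            if start in seen:
                continue
            comp = {start}
            queue = deque([start])
            while queue:
                u = queue.popleft()
                for v in self._adj[u]:
                    if v not in comp:
                        comp.add(v)
                        queue.append(v)
            seen |= comp
            comps.append(comp)
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def bfs_distances(self, source: str) -> dict[str, int]:
        """Unweighted shortest-path lengths from ``source`` to reachable nodes."""
        dist = {source: 0}
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for v in self._adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        return dist


def write_graphml(net: Network, path) -> None:
    """Export a network as GraphML (undirected; edge weights when present)."""
    from xml.sax.saxutils import escape

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '  <key id="w" for="edge" attr.name="weight" attr.type="double"/>',
        '  <graph edgedefault="undirected">',
    ]
    for node in net.nodes:
        lines.append(f'    <node id="{escape(node)}"/>')
    pairs = net.edges() + sorted((s, s) for s in net.self_loops)
    for a, b in pairs:
        weight = net.weights.get((a, b))
        if weight is None:
            lines.append(f'    <edge source="{escape(a)}" target="{escape(b)}"/>')
        else:
            lines.append(
                f'    <edge source="{escape(a)}" target="{escape(b)}">'
                f'<data key="w">{weight}</data></edge>'
            )
    lines += ["  </graph>", "</graphml>", ""]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_network(
    corpus: InteractionCorpus, keep_self_loops: bool = False, weighted: bool = False
) -> Network:
    """Build a deduplicated undirected network from an interaction corpus.

    Self-pairs are dropped unless ``keep_self_loops``; with ``weighted`` the
    evidence count of the (merged) record becomes the edge weight. An empty
    corpus yields an empty network.
    """
    net = Network(simple=not keep_self_loops)
    weight_acc: dict[tuple[str, str], float] = {}
    for rec in corpus.records:
        a, b = rec.pair
        if a == b and not keep_self_loops:
            continue
        key = (a, b)
        weight_acc[key] = weight_acc.get(key, 0) + rec.evidence_count
        net.add_edge(a, b)
    if weighted:
        for key, w in weight_acc.items():
            net.weights[key] = w
    return net


def extract_family_subnetwork(net: Network, family: Iterable[str]) -> Network:
    """Sub-network induced on the family plus its direct interactors.

    Returns the induced subgraph on ``family ∪ N(family)`` — including all
    interactor-interactor edges, so the neighbourhood's own wiring is kept.
    Family members absent from the network are logged, not fatal.
    """
    family = {f.strip().upper() for f in family}
    if not family:
        raise ValueError("family set is empty")
    present = family & set(net._adj)
    missing = family - present
    if missing:
        logger.warning("family members absent from network: %s", ", ".join(sorted(missing)))
    closure = set(present)
    for f in present:
        closure |= net.neighbors(f)
    return net.subgraph(closure)


def extract_family_family_network(
    net: Network, family: Iterable[str], corpus: InteractionCorpus
) -> Network:
    """Weighted intra-family network with self-loops.

    Nodes are family members with at least one intra-family edge or
    self-loop; edge weights are the corpus evidence counts (publications
    and/or techniques). Density downstream excludes the self-loops.
    """
    family = {f.strip().upper() for f in family}
    out = Network(simple=False)
    weight_acc: dict[tuple[str, str], float] = {}
    for rec in corpus.records:
        a, b = rec.pair
        if a in family and b in family:
            weight_acc[(a, b)] = weight_acc.get((a, b), 0) + rec.evidence_count
    for (a, b), w in sorted(weight_acc.items()):
        out.add_edge(a, b, weight=w)
    return out


# ---------------------------------------------------------------------------
# whole-graph topology
# ---------------------------------------------------------------------------

def density(n_nodes: int, n_edges: int) -> float:
    """Simple-graph edge density 2E / (V(V-1)); self-loops must be excluded from E."""
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def compactness_class(n_nodes: int, n_edges: int) -> str:
    """Classify by the E ≃ V^k rule: dense when 1 < k < 2, sparse otherwise."""
    if n_nodes < 2 or n_edges < 1:
        return "sparse"
    k = math.log(n_edges) / math.log(n_nodes)
    return "dense" if 1.0 < k < 2.0 else "sparse"


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    radius: Optional[int]
    diameter: Optional[int]
    average_shortest_path: Optional[float]
    average_clustering: float
    n_components: int
    compactness_class: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_topology(net: Network, degree_lt2_as_zero: bool = False) -> TopologySummary:
    """Whole-graph statistics.

    Radius and diameter are computed on the largest connected component; the
    average shortest path is taken over connected node pairs only; average
    clustering is the mean local coefficient over nodes of degree >= 2 (nodes
    of lower degree have an undefined coefficient and are excluded unless
    ``degree_lt2_as_zero``). Self-loops are ignored throughout. Single-node
    networks have undefined distances, reported as ``None``.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot summarize an empty network")
    comps = net.components()
    largest = comps[0]
    radius = diameter = None
    if len(largest) > 1:
        eccs = []
        for n in largest:
            dist = net.bfs_distances(n)
            eccs.append(max(dist.values()))
        radius, diameter = min(eccs), max(eccs)
    path_sum = 0
    path_count = 0
    for comp in comps:
        if len(comp) < 2:
            continue
        for n in comp:
            dist = net.bfs_distances(n)
            path_sum += sum(dist.values())
            path_count += len(dist) - 1
    avg_path = (path_sum / path_count) if path_count else None
    clustering = _local_clustering(net)
    if degree_lt2_as_zero:
        values = [c if not math.isnan(c) else 0.0 for c in clustering.values()]
    else:
        values = [c for c in clustering.values() if not math.isnan(c)]
    avg_clust = float(np.mean(values)) if values else 0.0
    return TopologySummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        density=density(net.n_nodes, net.n_edges),
        radius=radius,
        diameter=diameter,
        average_shortest_path=avg_path,
        average_clustering=avg_clust,
        n_components=len(comps),
        compactness_class=compactness_class(net.n_nodes, net.n_edges),
    )


# ---------------------------------------------------------------------------
# per-node metrics
# ---------------------------------------------------------------------------

def _local_clustering(net: Network) -> dict[str, float]:
    """Triangles / (deg choose 2); NaN for degree < 2 (undefined)."""
    out = {}
    for n in net.nodes:
        nbrs = net.neighbors(n)
        d = len(nbrs)
        if d < 2:
            out[n] = float("nan")
            continue
        links = 0
        nbr_list = sorted(nbrs)
        for i, u in enumerate(nbr_list):
            adj_u = net.neighbors(u)
            for v in nbr_list[i + 1 :]:
                if v in adj_u:
                    links += 1
        out[n] = 2.0 * links / (d * (d - 1))
    return out


def _betweenness(net: Network) -> dict[str, float]:
    """Brandes' algorithm; unnormalized, each unordered pair counted once."""
    bc = {n: 0.0 for n in net.nodes}
    for s in net.nodes:
        stack: list[str] = []
        pred: dict[str, list[str]] = {n: [] for n in net._adj}
        sigma = {n: 0.0 for n in net._adj}
        dist = {n: -1 for n in net._adj}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in net.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {n: 0.0 for n in net._adj}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {n: v / 2.0 for n, v in bc.items()}


def _core_numbers(net: Network) -> dict[str, int]:
    """k-core decomposition by iterative minimum-degree (bucket) peeling."""
    degrees = {n: len(net.neighbors(n)) for n in net.nodes}
    if not degrees:
        return {}
    max_deg = max(degrees.values())
    buckets: list[list[str]] = [[] for _ in range(max_deg + 1)]
    for n in sorted(degrees):
        buckets[degrees[n]].append(n)
    core: dict[str, int] = {}
    current = dict(degrees)
    removed: set[str] = set()
    k = 0
    for d in range(max_deg + 1):
        bucket = buckets[d]
        while bucket:
            n = bucket.pop()
            if n in removed or current[n] != d:
                continue
            k = max(k, d)
            core[n] = k
            removed.add(n)
            for nbr in net.neighbors(n):
                if nbr not in removed and current[nbr] > d:
                    current[nbr] -= 1
                    buckets[current[nbr]].append(nbr)
    # nodes whose stored degree went stale were re-bucketed; any stragglers
    # (isolated nodes) carry core 0 and were handled in the d=0 pass
    return core


def _eigenvector(net: Network, tol: float = 1e-10, max_iter: int = 100000) -> dict[str, float]:
    """Principal-eigenvector centrality by shifted power iteration.

    Iterates ``x <- (A + I) x`` (same eigenvectors as A, but the shift rules
    out sign-alternation on bipartite components), starting from a uniform
    positive vector, until the max-normalized vector changes by less than
    ``tol``. The result has maximum entry 1.
    """
    nodes = net.nodes
    if not nodes:
        raise ValueError("eigenvector centrality undefined on an empty graph")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for a, b in net.edges():
        rows.append(index[a])
        cols.append(index[b])
    x = np.ones(n)
    adj_rows = np.array(rows, dtype=np.int64)
    adj_cols = np.array(cols, dtype=np.int64)
    for _ in range(max_iter):
        nxt = x.copy()  # the +I shift
        if len(adj_rows):
            np.add.at(nxt, adj_rows, x[adj_cols])
            np.add.at(nxt, adj_cols, x[adj_rows])
        nxt /= nxt.max()
        if np.max(np.abs(nxt - x)) < tol:
            x = nxt
            break
        x = nxt
    return {node: float(x[index[node]]) for node in nodes}


@dataclass
class NodeMetrics:
    """Per-node degree, centralities, clustering and core number.

    Backed by a DataFrame indexed by node symbol with columns ``degree``,
    ``betweenness``, ``closeness``, ``eccentricity``, ``eigenvector``,
    ``local_clustering`` (NaN where degree < 2) and ``core_number``.
    """

    frame: pd.DataFrame

    @property
    def nodes(self) -> list[str]:
        return list(self.frame.index)

    def column(self, name: str) -> pd.Series:
        return self.frame[name]


def node_metrics(net: Network) -> NodeMetrics:
    """Compute the full per-node metric table for a simple undirected network.

    Self-loops, if present, are ignored by every metric. Closeness uses the
    legacy convention 1 / sum(d) with unreachable pairs contributing
    distance |V|; eccentricity is within the node's own component.
    """
    nodes = net.nodes
    if not nodes:
        raise ValueError("node_metrics requires a non-empty network")
    n = len(nodes)
    closeness = {}
    eccentricity = {}
    for node in nodes:
        dist = net.bfs_distances(node)
        reach_sum = sum(dist.values())
        unreachable = n - len(dist)
        closeness[node] = 1.0 / (reach_sum + unreachable * n) if n > 1 else 0.0
        eccentricity[node] = max(dist.values()) if len(dist) > 1 else 0
    frame = pd.DataFrame(
        {
            "degree": pd.Series({x: len(net.neighbors(x)) for x in nodes}),
            "betweenness": pd.Series(_betweenness(net)),
            "closeness": pd.Series(closeness),
            "eccentricity": pd.Series(eccentricity),
            "eigenvector": pd.Series(_eigenvector(net)),
            "local_clustering": pd.Series(_local_clustering(net)),
            "core_number": pd.Series(_core_numbers(net)),
        }
    ).loc[nodes]
    return NodeMetrics(frame=frame)


# ---------------------------------------------------------------------------
# hub classification and group comparisons
# ---------------------------------------------------------------------------

@dataclass
class HubReport:
    mean_degree: float
    hubs: frozenset
    table: tuple[tuple[int, int], tuple[int, int]]
    test: Optional[_stats.TestResult]
    degenerate: bool = False

    @property
    def hub_fraction(self) -> float:
        a, b = self.table[0]
        c, d = self.table[1]
        total = a + b + c + d
        return (a + c) / total if total else 0.0


def classify_hubs(metrics: NodeMetrics, family: Iterable[str]) -> HubReport:
    """Flag hubs (degree strictly above the mean) and test family association.

    Emits the 2x2 (family vs rest) x (hub vs non-hub) table with its Pearson
    chi-square p-value. A degenerate table (empty margin, e.g. when no node
    exceeds the mean) is flagged instead of raising.
    """
    family = {f.strip().upper() for f in family}
    if not family:
        raise ValueError("family set is empty")
    degrees = metrics.column("degree")
    mean_degree = float(degrees.mean())
    hub_flags = degrees > mean_degree
    in_family = pd.Series([n in family for n in metrics.nodes], index=degrees.index)
    a = int((hub_flags & in_family).sum())
    b = int((~hub_flags & in_family).sum())
    c = int((hub_flags & ~in_family).sum())
    d = int((~hub_flags & ~in_family).sum())
    table = ((a, b), (c, d))
    try:
        test = _stats.chi_square_2x2(table)
        degenerate = False
    except DegenerateTableError:
        test = None
        degenerate = True
    return HubReport(
        mean_degree=mean_degree,
        hubs=frozenset(degrees.index[hub_flags]),
        table=table,
        test=test,
        degenerate=degenerate,
    )


def group_threshold_chisquare(
    metrics: NodeMetrics, family: Iterable[str], metric_name: str, threshold: float
) -> _stats.TestResult:
    """Chi-square on (family membership) x (metric strictly above threshold)."""
    family = {f.strip().upper() for f in family}
    if metric_name not in metrics.frame.columns:
        raise ValueError(f"unknown metric {metric_name!r}")
    values = metrics.column(metric_name)
    above = values > threshold
    in_family = pd.Series([n in family for n in metrics.nodes], index=values.index)
    table = (
        (int((above & in_family).sum()), int((~above & in_family).sum())),
        (int((above & ~in_family).sum()), int((~above & ~in_family).sum())),
    )
    return _stats.chi_square_2x2(table)  # DegenerateTableError propagates


# ---------------------------------------------------------------------------
# power-law degree-distribution fit
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    ks_statistic: float
    p_value: float
    n_tail: int


def _discrete_alpha_mle(tail: np.ndarray, xmin: int) -> float:
    """Maximum-likelihood exponent for P(x) ∝ x^-alpha, x >= xmin (discrete)."""
    log_sum = float(np.log(tail).sum())
    n = len(tail)

    def nll(alpha: float) -> float:
        return alpha * log_sum + n * math.log(special.zeta(alpha, xmin))

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


def _tail_ks(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """KS distance between the empirical tail CDF and the fitted zeta CDF.

    Both CDFs are step functions on the same integer support, so the
    supremum is attained at a support point; no left-limit term is needed.
    """
    values, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / len(tail)
    z = special.zeta(alpha, xmin)
    fitted = 1.0 - special.zeta(alpha, values + 1) / z
    return float(np.abs(ecdf - fitted).max())


def fit_power_law(
    degrees: Sequence[int],
    xmin: Optional[int] = None,
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> PowerLawFit:
    """Fit a discrete power law to a degree sample.

    For each candidate ``xmin`` (every distinct positive degree unless fixed
    by the caller) the exponent is estimated by discrete maximum likelihood
    over the tail ``x >= xmin`` and the Kolmogorov-Smirnov distance between
    the empirical and fitted tail CDFs is computed; the ``xmin`` minimizing
    the KS distance wins. The p-value of the attained KS statistic comes from
    the analytic Kolmogorov distribution; with ``bootstrap_reps > 0`` a
    semi-parametric bootstrap p-value (fraction of synthetic samples with a
    larger refitted KS) is computed instead.
    """
    arr = np.asarray([d for d in degrees if d > 0], dtype=np.int64)
    if len(np.unique(arr)) < 2:
        raise FitUndefinedError("power-law fit undefined: fewer than 2 distinct degrees")
    if len(np.unique(arr)) < 10:
        raise ValueError("need at least 10 distinct degree values")
    if xmin is not None:
        candidates = [int(xmin)]
    else:
        uniq = np.unique(arr)
        candidates = [int(x) for x in uniq[:-1]]  # need >= 2 distinct tail values
    best: Optional[PowerLawFit] = None
    for cand in candidates:
        tail = arr[arr >= cand]
        if len(np.unique(tail)) < 2 or len(tail) < 10:
            continue
        alpha = _discrete_alpha_mle(tail, cand)
        ks = _tail_ks(tail, alpha, cand)
        if best is None or ks < best.ks_statistic:
            best = PowerLawFit(alpha=alpha, xmin=cand, ks_statistic=ks, p_value=0.0, n_tail=len(tail))
    if best is None:
        raise FitUndefinedError("no feasible xmin candidate")
    if bootstrap_reps > 0:
        best = PowerLawFit(
            alpha=best.alpha,
            xmin=best.xmin,
            ks_statistic=best.ks_statistic,
            p_value=_bootstrap_pvalue(arr, best, bootstrap_reps, seed),
            n_tail=best.n_tail,
        )
    else:
        best = PowerLawFit(
            alpha=best.alpha,
            xmin=best.xmin,
            ks_statistic=best.ks_statistic,
            p_value=float(special.kolmogorov(math.sqrt(best.n_tail) * best.ks_statistic)),
            n_tail=best.n_tail,
        )
    return best


def sample_discrete_power_law(
    alpha: float, xmin: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from the discrete power law by inverting the zeta tail CDF."""
    # precompute CDF up to a far tail cap; mass beyond the cap is negligible
    cap = max(10000, xmin * 1000)
    xs = np.arange(xmin, cap + 1)
    pmf = xs.astype(float) ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(xs, size=size, p=pmf)


def _bootstrap_pvalue(
    arr: np.ndarray, fit: PowerLawFit, reps: int, seed: int
) -> float:
    """Clauset-style semi-parametric bootstrap of the KS statistic."""
    rng = np.random.default_rng(seed)
    body = arr[arr < fit.xmin]
    n_tail = fit.n_tail
    n = len(arr)
    exceed = 0
    for _ in range(reps):
        tail_draw = rng.binomial(n, n_tail / n)
        synth_tail = sample_discrete_power_law(fit.alpha, fit.xmin, tail_draw, rng)
        if len(body):
            synth_body = rng.choice(body, size=n - tail_draw, replace=True)
            synth = np.concatenate([synth_body, synth_tail])
        else:
            synth = synth_tail
        try:
            refit = fit_power_law(synth)
        except (ValueError, FitUndefinedError):
            continue
        if refit.ks_statistic >= fit.ks_statistic:
            exceed += 1
    return exceed / reps if reps else float("nan")
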