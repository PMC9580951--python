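"""Clique enumeration for protein-complex prediction.

Maximal cliques are enumerated with the Bron-Kerbosch algorithm using
degeneracy ordering for the outer level and max-intersection pivoting
within, which is output-sensitive on the sparse networks that arise here.
All cliques (not only maximal ones) are obtained by expanding subsets of the
maximal cliques with deduplication. A clique family can also be turned back
into a graph (union of all within-set edges), which supports fixed-point
validation of published clique tables: reconstructing the graph from a
published maximal-clique list and re-enumerating must recover the list.

Self-loops are ignored throughout; output ordering is fully deterministic
(each clique sorted internally, cliques sorted lexicographically).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .network_core import Network


@dataclass(frozen=True)
class CliqueSet:
    """A deterministic collection of cliques of size >= ``min_size``."""

    cliques: tuple[tuple[str, ...], ...]
    min_size: int
    maximal: bool

    def __len__(self) -> int:
        return len(self.cliques)

    def __iter__(self):
        return iter(self.cliques)

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(c) for c in self.cliques}

    def size_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for c in self.cliques:
            hist[len(c)] = hist.get(len(c), 0) + 1
        return dict(sorted(hist.items()))


def _degeneracy_order(adj: dict[str, set[str]]) -> list[str]:
    """Peeling order by repeated minimum degree (ties by label)."""
    degree = {v: len(nbrs) for v, nbrs in adj.items()}
    buckets: dict[int, set[str]] = {}
    for v, d in degree.items():
        buckets.setdefault(d, set()).add(v)
    order = []
    removed: set[str] = set()
    while len(order) < len(adj):
        d = min(k for k, bucket in buckets.items() if bucket)
        v = min(buckets[d])
        buckets[d].discard(v)
        removed.add(v)
        order.append(v)
        for u in adj[v]:
            if u not in removed:
                buckets[degree[u]].discard(u)
                degree[u] -= 1
                buckets.setdefault(degree[u], set()).add(u)
        buckets = {k: b for k, b in buckets.items() if b}
    return order


def _bron_kerbosch_pivot(
    adj: dict[str, set[str]], r: list[str], p: set[str], x: set[str], out: list[frozenset[str]]
) -> None:
    if not p and not x:
        out.append(frozenset(r))
        return
    pivot = max(p | x, key=lambda u: (len(p & adj[u]), u))
    for v in sorted(p - adj[pivot]):
        _bron_kerbosch_pivot(adj, r + [v], p & adj[v], x & adj[v], out)
        p.discard(v)
        x.add(v)


def maximal_cliques(net: Network, min_size: int = 3) -> CliqueSet:
    """Enumerate all maximal cliques of size >= ``min_size``.

    Bron-Kerbosch over the degeneracy order with pivoting; self-loops are
    ignored. ``min_size`` must be at least 2 (a lone node is not a complex).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    adj = {v: set(net.neighbors(v)) for v in net.nodes}
    found: list[frozenset[str]] = []
    order = _degeneracy_order(adj)
    position = {v: i for i, v in enumerate(order)}
    for v in order:
        later = {u for u in adj[v] if position[u] > position[v]}
        earlier = {u for u in adj[v] if position[u] < position[v]}
        _bron_kerbosch_pivot(adj, [v], later, earlier, found)
    kept = sorted(tuple(sorted(c)) for c in found if len(c) >= min_size)
    return CliqueSet(cliques=tuple(kept), min_size=min_size, maximal=True)


def enumerate_cliques(net: Network, min_size: int = 3) -> CliqueSet:
    """Enumerate ALL complete subgraphs of size >= ``min_size``.

    Every clique lies inside some maximal clique of at least the same size,
    so the maximal cliques are expanded into their subsets of admissible size
    and deduplicated.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    maximal = maximal_cliques(net, min_size=min_size)
    seen: set[frozenset[str]] = set()
    for clique in maximal:
        for k in range(min_size, len(clique) + 1):
            for sub in combinations(clique, k):
                seen.add(frozenset(sub))
    kept = sorted(tuple(sorted(c)) for c in seen)
    return CliqueSet(cliques=tuple(kept), min_size=min_size, maximal=False)


def reconstruct_from_cliques(clique_list: Iterable[Iterable[str]]) -> Network:
    """Build the graph whose edges are the union of all within-clique pairs.

    Idempotent under repeated sets. A singleton set is rejected: it carries
    no edge and would silently vanish from the reconstruction.
    """
    net = Network(simple=True)
    n_sets = 0
    for members in clique_list:
        members = sorted(set(members))
        n_sets += 1
        if len(members) < 2:
            raise ValueError(f"clique {members!r} has fewer than 2 members")
        for a, b in combinations(members, 2):
            net.add_edge(a, b)
    if n_sets == 0:
        raise ValueError("empty clique list")
    return net
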