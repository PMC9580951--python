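"""Hypergeometric gene-set enrichment and pathway-involvement profiling.

Given a signature (e.g. the non-family direct interactors of the bromodomain
family) and a GMT-derived collection with a declared background size N, each
set of size K with overlap k is scored with the upper-tail hypergeometric
probability P(X >= k), followed by Benjamini-Hochberg FDR across the
collection. The default background of 23,467 genes is the conventional
protein-coding universe used by standard enrichment tooling and is always
overridable.

Beyond whole-signature enrichment the module profiles per-family-protein
pathway involvement (how many of a protein's direct interactors belong to
each selected pathway, row-normalized across the selected pathways) and
extracts bipartite family-to-pathway-member sub-networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .network_core import Network
from .stats import benjamini_hochberg, hypergeometric_tail

#: default declared background: the protein-coding gene universe size used by
#: common hypergeometric-enrichment tools
DEFAULT_BACKGROUND = 23467


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions and a declared background size."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    background: int = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background size must be positive")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set's overlap with a signature and its significance."""

    name: str
    size: int
    overlap: int
    hits: tuple[str, ...]
    p_value: float
    fdr: float


def enrich(signature: Iterable[str], collection: GeneSetCollection) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of a signature against every set.

    Per set: k = |signature ∩ set|, p = P(X >= k) under the hypergeometric
    with population N (declared background), K = set size, n = signature
    size. FDR is Benjamini-Hochberg across the whole collection. Rows come
    back sorted ascending by (fdr, p, name); hit symbols are sorted for
    byte-stable output.
    """
    signature = {s.strip().upper() for s in signature if s.strip()}
    if not signature:
        raise ValueError("signature is empty")
    N = collection.background
    if N < len(signature):
        raise ValueError(f"background {N} smaller than signature ({len(signature)})")
    names = sorted(collection.sets)
    p_values = []
    partial = []
    for name in names:
        members = collection.sets[name]
        if len(members) > N:
            raise ValueError(f"set {name!r} larger than background {N}")
        hits = tuple(sorted(signature & members))
        p = hypergeometric_tail(N, len(members), len(signature), len(hits))
        p_values.append(p)
        partial.append((name, len(members), hits, p))
    fdrs = benjamini_hochberg(p_values)
    rows = [
        EnrichmentRow(
            name=name, size=size, overlap=len(hits), hits=hits,
            p_value=p, fdr=float(max(q, p)),
        )
        for (name, size, hits, p), q in zip(partial, fdrs)
    ]
    rows.sort(key=lambda r: (r.fdr, r.p_value, r.name))
    return rows


def membership_pvalues(family: Iterable[str], collection: GeneSetCollection) -> list[EnrichmentRow]:
    """Enrichment of the family itself: which sets curate family members."""
    return enrich(family, collection)


def select_top_pathways(
    rows: Sequence[EnrichmentRow], max_n: int, fdr_cut: float
) -> list[str]:
    """First ``max_n`` pathway names with fdr < ``fdr_cut``, in ``rows`` order."""
    selected = [r.name for r in rows if r.fdr < fdr_cut]
    return selected[:max_n]


@dataclass
class InvolvementProfile:
    """Family-protein x pathway interactor counts plus a row-normalized copy.

    ``raw`` holds, for each family protein, the number of its direct
    non-family interactors belonging to each selected pathway. ``normalized``
    divides each row by its total across the selected pathways; rows with a
    zero total stay zero and are listed in ``zero_rows``.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    zero_rows: tuple[str, ...]


def involvement_profile(
    net: Network,
    family: Iterable[str],
    collection: GeneSetCollection,
    selected: Sequence[str],
) -> InvolvementProfile:
    """Count direct pathway-member interactors per family protein.

    For family protein f and pathway P: count distinct direct interactors of
    f in the global network that belong to P, excluding family members from
    the counting (the profile is about non-family partners). An interactor
    in several pathways counts once per pathway.
    """
    family = sorted({f.strip().upper() for f in family})
    unknown = [p for p in selected if p not in collection.sets]
    if unknown:
        raise ValueError(f"selected pathways not in collection: {unknown}")
    family_set = set(family)
    counts = np.zeros((len(family), len(selected)), dtype=np.int64)
    for i, f in enumerate(family):
        if not net.has_node(f):
            continue
        partners = net.neighbors(f) - family_set
        for j, pathway in enumerate(selected):
            counts[i, j] = len(partners & collection.sets[pathway])
    raw = pd.DataFrame(counts, index=family, columns=list(selected))
    totals = raw.sum(axis=1)
    normalized = raw.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    zero_rows = tuple(totals.index[totals == 0])
    return InvolvementProfile(raw=raw, normalized=normalized, zero_rows=zero_rows)


@dataclass
class PathwaySubnetwork:
    """Bipartite family-to-pathway-member sub-network."""

    network: Network
    family_retained: tuple[str, ...]

    @property
    def n_family_retained(self) -> int:
        return len(self.family_retained)


def pathway_subnetwork(
    net: Network, family: Iterable[str], pathway_set: Iterable[str]
) -> PathwaySubnetwork:
    """Extract family nodes with >= 1 interactor in the pathway set.

    The result contains those family nodes, their pathway-member
    interactors, and only the family-to-interactor edges (bipartite style:
    wiring among the interactors themselves is not carried over).
    """
    family = sorted({f.strip().upper() for f in family})
    members = {m.strip().upper() for m in pathway_set}
    sub = Network(simple=True)
    retained = []
    for f in family:
        if not net.has_node(f):
            continue
        partners = sorted(net.neighbors(f) & members)
        if partners:
            retained.append(f)
            for p in partners:
                sub.add_edge(f, p)
    return PathwaySubnetwork(network=sub, family_retained=tuple(retained))
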