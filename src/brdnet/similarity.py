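"""Family distance matrices and neighbourhood-overlap similarity.

Distances between family members are shortest-path lengths over the *global*
network, so paths may traverse non-family nodes. Similarity between two
family members i and j at radius s compares their exact-distance-s
neighbourhoods: S_ij = |N_s(i) ∩ N_s(j)| / |N_s(i) ∪ N_s(j)|, with i and j
removed from both sets. At s = 1 this is the classic Jaccard similarity of
direct-neighbour sets; at s = 2 or 3 it is the extended ("modified")
similarity that scores shared indirect interactors. The union denominator is
deliberate — the sum-of-sizes alternative caps scores at 0.5 and cannot
express near-identical neighbourhoods (a ``denominator="sum"`` variant is
kept for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .network_core import Network, UNREACHABLE


@dataclass
class DistanceMatrix:
    """Symmetric family-by-family shortest-path matrix (``UNREACHABLE`` = -1)."""

    frame: pd.DataFrame
    sentinel: int = UNREACHABLE

    @property
    def labels(self) -> list[str]:
        return list(self.frame.index)


@dataclass
class SimilarityMatrix:
    """Symmetric family-by-family similarity scores in [0, 1] at radius ``s``."""

    frame: pd.DataFrame
    s: int

    @property
    def labels(self) -> list[str]:
        return list(self.frame.index)

    def mean_off_diagonal(self) -> float:
        values = self.frame.to_numpy()
        n = values.shape[0]
        if n < 2:
            return 0.0
        mask = ~np.eye(n, dtype=bool)
        return float(values[mask].mean())


def family_distance_matrix(net: Network, family: Iterable[str]) -> DistanceMatrix:
    """BFS shortest-path lengths between family members over the global network.

    Family members missing from the network get a sentinel-filled row/column
    (diagonal stays 0); they are reported via the return value, not fatal.
    """
    labels = sorted({f.strip().upper() for f in family})
    if not labels:
        raise ValueError("family set is empty")
    n = len(labels)
    mat = np.full((n, n), UNREACHABLE, dtype=np.int64)
    np.fill_diagonal(mat, 0)
    for i, src in enumerate(labels):
        if not net.has_node(src):
            continue
        dist = net.bfs_distances(src)
        for j, dst in enumerate(labels):
            if dst in dist:
                mat[i, j] = dist[dst]
    frame = pd.DataFrame(mat, index=labels, columns=labels)
    return DistanceMatrix(frame=frame)


def neighborhood_at_distance(net: Network, node: str, s: int) -> set[str]:
    """Nodes at shortest-path distance EXACTLY ``s`` from ``node``.

    Not "within s": the ring at distance s. The focal node is never included.
    """
    if s < 1:
        raise ValueError("radius s must be >= 1")
    if not net.has_node(node):
        raise ValueError(f"node {node!r} not in network")
    dist = net.bfs_distances(node)
    return {v for v, d in dist.items() if d == s}


def similarity_matrix(
    net: Network,
    family: Iterable[str],
    s: int,
    denominator: str = "union",
    include_focal: bool = False,
) -> SimilarityMatrix:
    """Pairwise neighbourhood-overlap similarity at exact radius ``s``.

    For each ordered-free pair (i, j): the distance-s neighbourhoods are
    computed, i and j are removed from both sets (unless ``include_focal``),
    and the score is |intersection| / |union| (or, with
    ``denominator="sum"``, |intersection| / (|N_i| + |N_j|), which is
    mathematically capped at 0.5). Pairs with an empty union score 0 by
    convention; the diagonal is 1 whenever the node has a non-empty
    neighbourhood at radius s.
    """
    if s not in (1, 2, 3):
        raise ValueError("radius s must be 1, 2 or 3")
    if denominator not in ("union", "sum"):
        raise ValueError("denominator must be 'union' or 'sum'")
    labels = sorted({f.strip().upper() for f in family})
    if not labels:
        raise ValueError("family set is empty")
    rings: dict[str, set[str]] = {}
    for f in labels:
        rings[f] = neighborhood_at_distance(net, f, s) if net.has_node(f) else set()
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            a, b = labels[i], labels[j]
            ring_a, ring_b = rings[a], rings[b]
            if not include_focal:
                ring_a = ring_a - {a, b}
                ring_b = ring_b - {a, b}
            inter = len(ring_a & ring_b)
            if denominator == "union":
                denom = len(ring_a | ring_b)
            else:
                denom = len(ring_a) + len(ring_b)
            mat[i, j] = mat[j, i] = inter / denom if denom else 0.0
    frame = pd.DataFrame(mat, index=labels, columns=labels)
    return SimilarityMatrix(frame=frame, s=s)


def hierarchical_order(matrix: DistanceMatrix | SimilarityMatrix) -> list[str]:
    """Average-linkage leaf order for heatmap display.

    Similarity matrices are converted to dissimilarities (max - S); distance
    matrices use their values directly with unreachable sentinels replaced by
    one step beyond the largest finite distance. Labels are sorted before
    clustering so ties break lexicographically and the ordering is
    deterministic.
    """
    frame = matrix.frame.copy()
    if not frame.index.equals(frame.columns):
        raise ValueError("matrix must be square with matching labels")
    values = frame.to_numpy(dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError("matrix must be symmetric")
    labels = sorted(frame.index)
    values = frame.loc[labels, labels].to_numpy(dtype=float)
    if isinstance(matrix, SimilarityMatrix):
        dissim = values.max() - values
    else:
        finite_max = values[values >= 0].max(initial=0.0)
        dissim = np.where(values < 0, finite_max + 1.0, values)
    np.fill_diagonal(dissim, 0.0)
    if len(labels) < 3:
        return labels
    linkage = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    leaves = hierarchy.leaves_list(linkage)
    return [labels[i] for i in leaves]
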