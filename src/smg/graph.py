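"""Correlation calling, correlation graphs, clusters and graph differences.

Two taxa are *positively correlated* when the slope-based distance between
their scaled profiles is strictly below ``n - 1`` (``n`` samples); a taxon is
*negatively correlated* with a target when it is positively correlated with
the target's negated (then rescaled) profile.  Positive correlations define
an undirected graph whose connected components are interpreted as clusters
of co-varying taxa; between-condition change is the symmetric difference of
two such graphs on a common vertex set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    _minmax_rows,
    _ordered_pair_sum,
    _scale_vector,
    opposite_profile,
    slope_distance,
    validate_table,
)

__all__ = [
    "is_positive_correlation",
    "is_negative_correlation",
    "negative_edges",
    "build_positive_graph",
    "connected_components",
    "average_degree",
    "symmetric_difference",
    "GraphDiff",
]


def canonical_edge(u, v) -> tuple:
    """Store undirected edges as lexicographically sorted pairs."""
    return (u, v) if str(u) <= str(v) else (v, u)


def is_positive_correlation(dist: float, n_samples: int) -> bool:
    """Is a slope distance below the positive-correlation threshold?

    The threshold is ``n_samples - 1``, half the distance ``2(n - 1)``
    separating the indicative profiles ``O`` and ``P``; the comparison is
    strict (a distance of exactly ``n - 1`` is *not* a positive correlation).
    Borderline values are classified by plain IEEE comparison.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    if dist < 0:
        raise ValueError(f"distance must be non-negative, got {dist}")
    return dist < n_samples - 1


def is_negative_correlation(row_a, row_b) -> bool:
    """Is profile ``B`` negatively correlated with target profile ``A``?

    True when ``d(scaled(A-), scaled(B)) < n - 1`` with ``A- = -A``; for a
    non-constant ``A`` this compares ``B`` against ``1 - scaled(A)``.  The
    relation is symmetric in ``A`` and ``B``.
    """
    row_a = np.asarray(row_a, dtype=float)
    row_b = np.asarray(row_b, dtype=float)
    if row_a.shape != row_b.shape or row_a.ndim != 1:
        raise ValueError(
            f"profiles must be 1-d and equal length, got {row_a.shape} and {row_b.shape}"
        )
    n = row_a.size
    if n < 2:
        raise ValueError("profiles need at least 2 samples")
    d = slope_distance(_scale_vector(opposite_profile(row_a)), _scale_vector(row_b))
    return is_positive_correlation(d, n)


def negative_edges(table: pd.DataFrame) -> set[tuple]:
    """All unordered taxon pairs in negative correlation.

    Computed as pairwise slope distances between each scaled profile and the
    scaled negations of all others; reported separately from the positive
    graph (negative links are not graph edges).
    """
    table = validate_table(table)
    values = table.to_numpy()
    n = values.shape[1]
    scaled = _minmax_rows(values)
    neg_scaled = _minmax_rows(-values)
    taxa = list(table.index)
    edges: set[tuple] = set()
    for a in range(len(taxa)):
        gamma = scaled[a + 1 :] - neg_scaled[a]
        if gamma.size == 0:
            continue
        dists = _ordered_pair_sum(gamma)
        for off, d in enumerate(dists, start=a + 1):
            if d < n - 1:
                edges.add(canonical_edge(taxa[a], taxa[off]))
    return edges


def build_positive_graph(
    dm: pd.DataFrame, n_samples: int | None = None, drop_all_zero: bool = False
) -> nx.Graph:
    """Positive-correlation graph from a slope-distance matrix.

    Parameters
    ----------
    dm : pandas.DataFrame
        Square symmetric distance matrix with taxon identifiers on both axes.
    n_samples : int, optional
        Number of samples behind the matrix, setting the edge threshold
        ``n_samples - 1``.  Required (the matrix itself does not carry it);
        accepted positionally or from ``dm.attrs['n_samples']``.
    drop_all_zero : bool, default False
        Unused placeholder kept for workflow symmetry; vertex removal is done
        on the abundance table before computing ``dm``.

    Returns
    -------
    networkx.Graph
        Vertices are all taxa; edge ``{u, v}`` present iff ``dm[u, v] < n - 1``.
        Each edge stores the distance in its ``distance`` attribute; the graph
        stores ``n_samples`` and ``threshold`` in ``G.graph``.
    """
    if n_samples is None:
        n_samples = dm.attrs.get("n_samples")
    if n_samples is None:
        raise ValueError("n_samples is required to set the n - 1 threshold")
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    if dm.shape[0] != dm.shape[1]:
        raise ValueError(f"distance matrix must be square, got {dm.shape}")
    threshold = n_samples - 1
    g = nx.Graph(n_samples=int(n_samples), threshold=float(threshold))
    taxa = list(dm.index)
    g.add_nodes_from(taxa)
    values = dm.to_numpy(dtype=float)
    ii, jj = np.nonzero(np.triu(values < threshold, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        u, v = canonical_edge(taxa[i], taxa[j])
        g.add_edge(u, v, distance=float(values[i, j]))
    return g


def connected_components(g: nx.Graph) -> list[set]:
    """Connected components (clusters of co-varying taxa).

    Deterministic output order: sorted by each component's smallest member
    taxon identifier.
    """
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: min(str(v) for v in c))


def average_degree(g: nx.Graph) -> float:
    """Average vertex degree, ``2|E| / |V|`` — the network density summary."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no vertices")
    return 2.0 * g.number_of_edges() / g.number_of_nodes()


@dataclass(frozen=True)
class GraphDiff:
    """Symmetric difference between two correlation graphs.

    Attributes
    ----------
    vertices : frozenset
        The (shared) vertex set.
    changed_edges : frozenset of tuple
        Edges present in exactly one of the two graphs.
    magnitude : int
        ``|E(G1 Δ G2)|`` — the number of changed edges, the scalar
        measure of between-condition network change.
    """

    vertices: frozenset
    changed_edges: frozenset = field(default_factory=frozenset)

    @property
    def magnitude(self) -> int:
        return len(self.changed_edges)

    def degrees(self) -> dict:
        """Per-vertex degree in the symmetric-difference graph."""
        deg = {v: 0 for v in self.vertices}
        for u, v in self.changed_edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.changed_edges)
        return g


def symmetric_difference(g1: nx.Graph, g2: nx.Graph) -> GraphDiff:
    """Symmetric difference ``G1 Δ G2`` of two graphs on the same vertices.

    ``E(G1 Δ G2) = E(G1) ∪ E(G2) - E(G1) ∩ E(G2)``.  A vertex-set
    mismatch is an error: harmonize the two conditions to a common taxon set
    first (e.g. with the pooled comparison filter), treating missing taxa as
    all-zero rows.
    """
    v1, v2 = set(g1.nodes), set(g2.nodes)
    if v1 != v2:
        raise ValueError(
            "graphs have different vertex sets; harmonize taxa across conditions "
            f"first ({len(v1 ^ v2)} mismatched vertices)"
        )
    e1 = {canonical_edge(u, v) for u, v in g1.edges}
    e2 = {canonical_edge(u, v) for u, v in g2.edges}
    return GraphDiff(vertices=frozenset(v1), changed_edges=frozenset(e1 ^ e2))
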