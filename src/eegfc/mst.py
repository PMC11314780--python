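"""Minimum spanning tree of a PLI matrix and its topology metrics.

The MST is built with Kruskal's algorithm on edge weights 1 - PLI, so
minimising total weight keeps the backbone of strongest phase couplings.
The tree's shape is summarised by seven metrics that locate it on the
line-like ... star-like continuum:

==================== =========================================================
leaf fraction  Lf    degree-1 nodes / N, in [2/N, (N-1)/N]
diameter             longest inter-node path, in edges
eccentricity         per node: longest path to any other node; mean reported
betweenness   Bc     fraction of shortest paths through a node, normalised by
                     (N-1)(N-2)/2 unordered pairs; mean and max reported
tree hierarchy Th    L / (2 m Bmax) with L the leaf *number* and m = N-1;
                     -> 0 for a line, 0.5 for a star
degree correlation   Pearson r of endpoint degrees over the 2m ordered edge
                     pairs (assortativity); negative = dissortative
kappa          K     <k^2>/<k>, degree divergence (hub heterogeneity)
==================== =========================================================

Note Th uses the leaf number in the numerator: only then does the star
configuration (L = m, Bmax = 1) reach the documented limit 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .spectral import ConnectivityMatrix

__all__ = [
    "SpanningTree",
    "MSTFeatureSet",
    "build_mst",
    "leaf_fraction",
    "diameter",
    "eccentricity",
    "betweenness",
    "tree_hierarchy",
    "degree_correlation",
    "kappa",
    "mst_features",
]


@dataclass
class SpanningTree:
    """N-node, (N-1)-edge acyclic connected graph with PLI edge strengths."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() < 2:
            raise ValueError("a spanning tree needs at least 2 nodes")
        if not nx.is_tree(g):
            raise ValueError("graph is not a tree (cycle or disconnection)")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in sorted(self.graph.degree)], dtype=float)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as (node_a, node_b, pli_weight), node_a < node_b."""
        out = []
        for a, b, attrs in self.graph.edges(data=True):
            a, b = (a, b) if a < b else (b, a)
            out.append((a, b, float(attrs.get("pli", np.nan))))
        return sorted(out)


def build_mst(pli: ConnectivityMatrix | np.ndarray) -> SpanningTree:
    """Kruskal MST on weights 1 - PLI (keeps the strongest couplings).

    Ties are broken deterministically: edges are considered in
    (weight, smaller index, larger index) order, so identical inputs always
    yield the identical tree.
    """
    values = pli.values if isinstance(pli, ConnectivityMatrix) else np.asarray(pli, dtype=float)
    n = values.shape[0]
    if values.ndim != 2 or values.shape[1] != n:
        raise ValueError("PLI matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 channels")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("PLI matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=1.0 - values[i, j], pli=values[i, j])
    # Kruskal with an explicit deterministic sort key; networkx's stable sort
    # on weight alone would depend on insertion order for ties.
    tree = nx.Graph()
    tree.add_nodes_from(range(n))
    uf = nx.utils.UnionFind(range(n))
    for i, j, attrs in sorted(
        g.edges(data=True), key=lambda e: (e[2]["weight"], e[0], e[1])
    ):
        if uf[i] != uf[j]:
            uf.union(i, j)
            tree.add_edge(i, j, **attrs)
            if tree.number_of_edges() == n - 1:
                break
    return SpanningTree(graph=tree)


def leaf_fraction(tree: SpanningTree) -> float:
    """Fraction of degree-1 nodes; 2/N for a line, (N-1)/N for a star."""
    deg = tree.degrees
    return float((deg == 1).sum() / tree.n_nodes)


def eccentricity(tree: SpanningTree) -> tuple[dict[int, int], float]:
    """Per-node longest unweighted path (in edges) and its mean."""
    ecc = nx.eccentricity(tree.graph)
    return ecc, float(np.mean(list(ecc.values())))


def diameter(tree: SpanningTree) -> int:
    """Longest unweighted path between any two nodes, in edges."""
    ecc, _ = eccentricity(tree)
    return int(max(ecc.values()))


def betweenness(tree: SpanningTree) -> tuple[dict[int, float], float, float]:
    """Normalised betweenness per node, its mean, and the maximum Bmax.

    Normalisation: unordered pairs excluding the node itself,
    (N-1)(N-2)/2 — the star centre scores exactly 1, every leaf 0.
    """
    if tree.n_nodes < 3:
        raise ValueError("betweenness undefined for N < 3 (no third-party pairs)")
    bc = nx.betweenness_centrality(tree.graph, normalized=True)
    vals = np.array(list(bc.values()))
    return bc, float(vals.mean()), float(vals.max())


def tree_hierarchy(tree: SpanningTree) -> float:
    """Th = L / (2 m Bmax): integration vs hub-overload trade-off in [0, 1]."""
    if tree.n_nodes < 3:
        raise ValueError("tree hierarchy undefined for N < 3")
    leaves = int((tree.degrees == 1).sum())
    m = tree.n_edges
    _, _, bmax = betweenness(tree)
    if bmax == 0:
        raise ValueError("Bmax is zero; degenerate tree")
    return float(leaves / (2.0 * m * bmax))


def degree_correlation(tree: SpanningTree) -> float:
    """Pearson r between endpoint degrees over both orientations of each edge.

    Returns NaN (undefined) when either marginal has zero variance, e.g. for
    a 2-node tree where both degrees are 1.
    """
    deg = dict(tree.graph.degree)
    xs, ys = [], []
    for a, b in tree.graph.edges:
        xs.extend((deg[a], deg[b]))
        ys.extend((deg[b], deg[a]))
    xs, ys = np.array(xs, dtype=float), np.array(ys, dtype=float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def kappa(tree: SpanningTree) -> float:
    """Degree divergence <k^2>/<k> over all N nodes."""
    deg = tree.degrees
    return float((deg**2).mean() / deg.mean())


@dataclass
class MSTFeatureSet:
    """The seven tree metrics (per-node ones as means; Bmax kept for Th)."""

    leaf_fraction: float
    diameter: int
    eccentricity_mean: float
    betweenness_mean: float
    betweenness_max: float
    tree_hierarchy: float
    degree_correlation: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "LeafFraction": self.leaf_fraction,
            "Diameter": float(self.diameter),
            "Eccentricity": self.eccentricity_mean,
            "BetweennessCentrality": self.betweenness_mean,
            "TreeHierarchy": self.tree_hierarchy,
            "DegreeCorrelation": self.degree_correlation,
            "Kappa": self.kappa,
        }


def mst_features(tree: SpanningTree) -> MSTFeatureSet:
    """All tree metrics in one bundle; identical to calling each individually."""
    _, ecc_mean = eccentricity(tree)
    _, bc_mean, bmax = betweenness(tree)
    return MSTFeatureSet(
        leaf_fraction=leaf_fraction(tree),
        diameter=diameter(tree),
        eccentricity_mean=ecc_mean,
        betweenness_mean=bc_mean,
        betweenness_max=bmax,
        tree_hierarchy=tree_hierarchy(tree),
        degree_correlation=degree_correlation(tree),
        kappa=kappa(tree),
    )
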