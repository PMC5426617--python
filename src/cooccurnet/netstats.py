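"""Summary statistics of interaction networks.

Five statistics characterize a derived network: average degree ⟨k⟩ = 2m/n,
mean shortest-path length, diameter, global clustering coefficient
(transitivity: the proportion of open triangles closed by a third edge), and
the maximum modularity found by greedy agglomeration. Path-based statistics
are computed on the largest connected component, since the mean path length
is undefined across components; the component count is reported alongside.

Fixed-partition modularity and the phylum mixing table quantify assortative
mixing of categorical (phylum) labels on the nodes of a network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .abundance import OTHER_PHYLUM

__all__ = [
    "NetworkStatistics",
    "average_degree",
    "mean_path_length",
    "diameter",
    "global_clustering",
    "max_modularity",
    "partition_modularity",
    "mixing_table",
    "compute_statistics",
    "summarize_ensemble",
]


class DegenerateGraphError(ValueError):
    """The requested statistic is undefined for this graph."""


def _require_nodes(g: nx.Graph, n_min: int, what: str) -> None:
    if g.number_of_nodes() < n_min:
        raise DegenerateGraphError(f"{what} requires at least {n_min} nodes")


def average_degree(g: nx.Graph, include_singletons: bool = False) -> float:
    """⟨k⟩ = 2m/n over the singleton-free node set.

    Degree-zero nodes are dropped before the ratio is taken (the reported
    convention; derived networks are singleton-free already). Pass
    ``include_singletons=True`` for the inclusive variant, which lowers ⟨k⟩
    whenever singletons are present.
    """
    if not include_singletons:
        g = g.subgraph([v for v, d in g.degree() if d > 0])
    n = g.number_of_nodes()
    if n < 1:
        raise DegenerateGraphError("average degree of an empty graph")
    return 2.0 * g.number_of_edges() / n


def _largest_component(g: nx.Graph) -> nx.Graph:
    if g.number_of_nodes() == 0:
        raise DegenerateGraphError("empty graph")
    comp = max(nx.connected_components(g), key=len)
    return g.subgraph(comp)


def _distance_matrix(g: nx.Graph) -> np.ndarray:
    adj = nx.to_scipy_sparse_array(g, weight=None, format="csr")
    return shortest_path(adj, method="D", directed=False, unweighted=True)


def mean_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over ordered node pairs, l = Σ dᵢⱼ / (n(n−1)).

    Computed on the largest connected component (the mean is undefined
    across components).
    """
    _require_nodes(g, 2, "mean path length")
    sub = _largest_component(g)
    if sub.number_of_nodes() < 2:
        raise DegenerateGraphError("largest component has a single node")
    d = _distance_matrix(sub)
    n = d.shape[0]
    return float(d.sum() / (n * (n - 1)))


def diameter(g: nx.Graph) -> int:
    """Longest shortest path (maximum dᵢⱼ) within the largest component."""
    _require_nodes(g, 2, "diameter")
    sub = _largest_component(g)
    if sub.number_of_nodes() < 2:
        raise DegenerateGraphError("largest component has a single node")
    return int(_distance_matrix(sub).max())


def global_clustering(g: nx.Graph) -> float:
    """Global clustering coefficient (transitivity).

    Matrix recipe: with adjacency Q, R = Q·Q counts length-2 paths between
    every node pair; U, the strict upper triangle of R, counts each
    connected triple once; Σ(U∘Q)/ΣU is then the proportion of open
    triangles closed by a third edge (equivalently 3·triangles / connected
    triples).
    """
    _require_nodes(g, 3, "clustering coefficient")
    q = nx.to_numpy_array(g, weight=None)
    r = q @ q
    u = np.triu(r, k=1)
    denom = u.sum()
    if denom == 0:
        raise DegenerateGraphError("no length-2 paths; clustering undefined")
    return float((u * q).sum() / denom)


def max_modularity(g: nx.Graph) -> Tuple[float, Dict[object, int]]:
    """Greedy agglomerative modularity maximization (CNM).

    Starts with every node in its own group and repeatedly merges the pair
    of groups with the best marginal modularity gain until one group
    remains, returning the maximum modularity along the merge path and its
    partition. Modularity of a partition is Σ_g (e_gg − a_g²), with e_gg
    the fraction of edges inside group g and a_g the fraction of edge
    endpoints in g. Deterministic for a fixed graph (igraph's fast-greedy
    implementation).
    """
    if g.number_of_edges() < 1:
        raise DegenerateGraphError("modularity of an edgeless graph")
    nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    h = ig.Graph(n=len(nodes), edges=edges)
    dendrogram = h.community_fastgreedy()
    clustering = dendrogram.as_clustering()
    q = h.modularity(clustering.membership)
    partition = {v: int(clustering.membership[index[v]]) for v in nodes}
    return float(q), partition


def partition_modularity(g: nx.Graph, labels: Mapping[object, str]) -> float:
    """Modularity of a fixed node partition given by categorical labels.

    Same Σ_g (e_gg − a_g²) score as :func:`max_modularity` but with no
    optimization: groups are the label classes (missing labels map to
    ``"Other"``). Zero when all nodes share one label.
    """
    if g.number_of_edges() < 1:
        raise DegenerateGraphError("modularity of an edgeless graph")
    groups: Dict[str, set] = {}
    for v in g.nodes():
        groups.setdefault(labels.get(v, OTHER_PHYLUM), set()).add(v)
    return float(nx.algorithms.community.modularity(g, groups.values()))


def mixing_table(
    g: nx.Graph,
    labels: Mapping[object, str],
    categories: Optional[list] = None,
) -> pd.DataFrame:
    """Fraction of edges joining each pair of label categories.

    Symmetric table: a within-category edge contributes 1/m to its diagonal
    cell; a cross-category edge contributes ½/m to each of its two symmetric
    off-diagonal cells, so all cells sum to exactly 1. An ``All`` row and
    column hold the marginals.
    """
    m = g.number_of_edges()
    if m < 1:
        raise DegenerateGraphError("mixing table of an edgeless graph")
    label_of = {v: labels.get(v, OTHER_PHYLUM) for v in g.nodes()}
    if categories is None:
        categories = sorted(set(label_of.values()))
    table = pd.DataFrame(0.0, index=categories, columns=categories)
    for u, v in g.edges():
        a, b = label_of[u], label_of[v]
        if a == b:
            table.loc[a, b] += 1.0 / m
        else:
            table.loc[a, b] += 0.5 / m
            table.loc[b, a] += 0.5 / m
    table["All"] = table.sum(axis=1)
    table.loc["All"] = table.sum(axis=0)
    return table


@dataclass
class NetworkStatistics:
    """The statistics bundle for one network."""

    n: int
    m: int
    n_components: int
    average_degree: float
    mean_path_length: Optional[float]
    diameter: Optional[int]
    clustering: Optional[float]
    max_modularity: Optional[float]

    def as_dict(self) -> Dict[str, float]:
        return {
            "n": self.n,
            "m": self.m,
            "n_components": self.n_components,
            "average_degree": self.average_degree,
            "mean_path_length": self.mean_path_length,
            "diameter": self.diameter,
            "clustering": self.clustering,
            "max_modularity": self.max_modularity,
        }


def compute_statistics(g: nx.Graph, include_modularity: bool = True) -> NetworkStatistics:
    """All summary statistics for one graph; undefined entries become None."""
    n = g.number_of_nodes()
    if n == 0:
        return NetworkStatistics(0, 0, 0, float("nan"), None, None, None, None)

    def _safe(fn):
        try:
            return fn(g)
        except DegenerateGraphError:
            return None

    return NetworkStatistics(
        n=n,
        m=g.number_of_edges(),
        n_components=nx.number_connected_components(g),
        average_degree=average_degree(g),
        mean_path_length=_safe(mean_path_length),
        diameter=_safe(diameter),
        clustering=_safe(global_clustering),
        max_modularity=(_safe(lambda x: max_modularity(x)[0]) if include_modularity else None),
    )


def summarize_ensemble(
    graphs, include_modularity: bool = True
) -> Tuple[pd.DataFrame, Dict[str, Dict[str, float]]]:
    """Per-replicate statistics table plus a {stat: {mean, sd, n}} summary.

    Replicates on which a statistic is undefined are dropped from that
    statistic's summary; the count ``n`` records how many contributed. The
    sd is the sample standard deviation (ddof=1).
    """
    rows = [compute_statistics(g, include_modularity=include_modularity).as_dict() for g in graphs]
    frame = pd.DataFrame(rows)
    frame.insert(0, "replicate", range(len(rows)))
    summary: Dict[str, Dict[str, float]] = {}
    for col in frame.columns:
        if col == "replicate":
            continue
        vals = pd.to_numeric(frame[col], errors="coerce").dropna()
        summary[col] = {
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "n": int(len(vals)),
        }
    return frame, summary
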