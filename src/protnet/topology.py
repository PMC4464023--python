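"""Topological metrics of interaction networks.

Assembles the metric vector used throughout: scale-free fitting index (SFFI),
average path length (APL), diameter, average clustering coefficient (ACC),
transitivity and Newman modularity.  Path-based metrics are computed on the
largest connected component (sparse random graphs at mean degree ~5 routinely
contain isolated nodes), matching the convention of averaging over connected
pairs only.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.stats import linregress

from .network_io import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyReport",
    "transitivity",
    "average_clustering_coefficient",
    "average_path_length",
    "diameter",
    "scale_free_fitting_index",
    "sffi_from_degrees",
    "modularity",
    "topology_report",
]


def _as_nx(network: InteractionNetwork | nx.Graph) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.to_networkx()


def transitivity(network: InteractionNetwork | nx.Graph) -> float:
    """Global clustering: 3 x triangles / connected triples, in [0, 1]."""
    g = _as_nx(network)
    if g.number_of_nodes() < 3:
        raise ValueError("transitivity needs at least 3 nodes")
    t = nx.transitivity(g)
    if t == 0 and all(d < 2 for _, d in g.degree()):
        warnings.warn("no connected triples; transitivity reported as 0")
    return float(t)


def average_clustering_coefficient(network: InteractionNetwork | nx.Graph) -> float:
    """Mean local (Watts–Strogatz) clustering; degree-<2 nodes contribute 0."""
    g = _as_nx(network)
    if g.number_of_nodes() < 3:
        raise ValueError("clustering needs at least 3 nodes")
    return float(nx.average_clustering(g, count_zeros=True))


def _component_distances(network: InteractionNetwork | nx.Graph) -> np.ndarray:
    """All-pairs shortest-path matrix of the largest connected component."""
    g = _as_nx(network)
    if g.number_of_edges() == 0:
        raise ValueError("path metrics undefined on an edgeless network")
    comp = max(nx.connected_components(g), key=len)
    nodes = sorted(comp)
    sub = nx.to_scipy_sparse_array(g.subgraph(nodes), nodelist=nodes, format="csr")
    return shortest_path(sparse.csr_matrix(sub), method="D", directed=False,
                         unweighted=True)


def average_path_length(network: InteractionNetwork | nx.Graph) -> float:
    """Mean shortest-path length over ordered reachable pairs, largest component."""
    d = _component_distances(network)
    n = d.shape[0]
    if n < 2:
        raise ValueError("largest component has fewer than 2 nodes")
    off = ~np.eye(n, dtype=bool)
    return float(d[off].mean())


def diameter(network: InteractionNetwork | nx.Graph) -> int:
    """Longest shortest path of the largest connected component."""
    d = _component_distances(network)
    return int(d.max())


def sffi_from_degrees(degrees) -> float:
    """SFFI of a raw degree sequence (degree-0 entries are ignored)."""
    degs = [d for d in degrees if d > 0]
    ks, counts = np.unique(degs, return_counts=True)
    if len(ks) < 3:
        raise ValueError("scale-free fitting index needs >= 3 distinct degrees")
    x = np.log10(ks)
    y = np.log10(counts / counts.sum())
    fit = linregress(x, y)
    return float(fit.rvalue ** 2)


def scale_free_fitting_index(network: InteractionNetwork | nx.Graph) -> float:
    """R² of the OLS line through (log10 k, log10 P(k)), unbinned.

    P(k) is the empirical frequency of degree k over degrees with nonzero
    frequency (k >= 1).  A perfect power-law degree distribution gives 1.0.
    """
    g = _as_nx(network)
    return sffi_from_degrees([d for _, d in g.degree()])


def modularity(network: InteractionNetwork | nx.Graph) -> float:
    """Newman modularity Q of the greedy agglomerative partition."""
    g = _as_nx(network)
    if g.number_of_edges() == 0:
        return 0.0
    communities = nx.community.greedy_modularity_communities(g)
    return float(nx.community.modularity(g, communities))


@dataclass
class TopologyReport:
    """The per-network metric vector (one summary-table row per network)."""

    n_nodes: int
    n_edges: int
    sffi: float | None
    apl: float
    diameter: int
    acc: float
    transitivity: float
    modularity: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv_row(self, label: str = "") -> str:
        sffi = "NA" if self.sffi is None else f"{self.sffi:.3f}"
        return (f"{label}\t{sffi}\t{self.apl:.3f}\t{self.diameter}\t"
                f"{self.transitivity:.3f}\t{self.acc:.3f}\t{self.modularity:.3f}")


def topology_report(network: InteractionNetwork | nx.Graph) -> TopologyReport:
    """Assemble the full metric vector; SFFI is None when undefined."""
    g = _as_nx(network)
    try:
        sffi: float | None = scale_free_fitting_index(g)
    except ValueError:
        logger.warning("SFFI undefined (fewer than 3 distinct degrees)")
        sffi = None
    d = _component_distances(g)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    return TopologyReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        sffi=sffi,
        apl=float(d[off].mean()) if n > 1 else math.nan,
        diameter=int(d.max()),
        acc=average_clustering_coefficient(g),
        transitivity=transitivity(g),
        modularity=modularity(g),
    )
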