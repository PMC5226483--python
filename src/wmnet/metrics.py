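"""Global and nodal graph metrics for weighted connectomes.

Path-based metrics treat edge length as the reciprocal of edge weight, so
stronger connections are shorter; this is the convention of the weighted
brain-network toolbox lineage.  The characteristic path length is the
harmonic-mean form (the reciprocal of global efficiency), which remains
finite when some node pairs are disconnected: a disconnected pair simply
contributes zero efficiency.

Metrics
-------
Cp    mean clustering coefficient on the binarized topology
Lp    characteristic path length, 1 / Eg
Eg    global efficiency, mean of 1/L_ij over ordered pairs
Eloc  mean over nodes of the global efficiency of the neighbor subgraph
B_nod unnormalized betweenness centrality over unordered pairs
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .construction import WeightedNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "PathLengthMatrix",
    "shortest_paths",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "betweenness",
    "global_metrics",
    "nodal_metrics",
]

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eg", "Eloc", "gamma", "lambda_", "sigma")


@dataclass
class GlobalMetrics:
    """Whole-network summary metrics for one subject's connectome.

    ``gamma``, ``lambda_`` and ``sigma`` are the small-world ratios against
    degree-preserving random networks; they are NaN until filled in by the
    null-model stage.
    """

    Cp: float
    Lp: float
    Eg: float
    Eloc: float
    gamma: float = float("nan")
    lambda_: float = float("nan")
    sigma: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in GLOBAL_METRIC_NAMES}


@dataclass
class NodalMetrics:
    """Per-node betweenness centrality and degree."""

    betweenness: np.ndarray
    degree: np.ndarray

    def __post_init__(self) -> None:
        self.betweenness = np.asarray(self.betweenness, dtype=float)
        self.degree = np.asarray(self.degree, dtype=int)


@dataclass(frozen=True)
class PathLengthMatrix:
    """All-pairs shortest path lengths; ``inf`` marks disconnected pairs."""

    lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]


def _length_graph(net: WeightedNetwork) -> csr_matrix:
    w = net.weights
    iu, ju = np.nonzero(np.triu(w, 1))
    lengths = 1.0 / w[iu, ju]
    n = net.n_nodes
    m = csr_matrix(
        (np.concatenate([lengths, lengths]), (np.concatenate([iu, ju]), np.concatenate([ju, iu]))),
        shape=(n, n),
    )
    return m


def shortest_paths(net: WeightedNetwork) -> PathLengthMatrix:
    """All-pairs weighted shortest paths with edge length 1/weight."""
    lengths = dijkstra(_length_graph(net), directed=False)
    np.fill_diagonal(lengths, 0.0)
    return PathLengthMatrix(lengths=lengths)


def clustering_coefficient(net: WeightedNetwork, weighted: bool = False) -> float:
    """Mean clustering coefficient Cp.

    The default counts realized edges among each node's neighbors on the
    binarized topology: cc_i = E_i / (d_i (d_i - 1) / 2), zero for degree
    below 2, averaged over all nodes.  ``weighted=True`` switches to the
    geometric-mean (Onnela) weighted variant.
    """
    return float(np.mean(nodal_clustering(net, weighted=weighted)))


def nodal_clustering(net: WeightedNetwork, weighted: bool = False) -> np.ndarray:
    a = (net.weights > 0).astype(float)
    deg = a.sum(axis=1)
    denom = deg * (deg - 1)
    if weighted:
        wmax = net.weights.max()
        if wmax == 0:
            return np.zeros(net.n_nodes)
        wh = np.cbrt(net.weights / wmax)
        tri = np.diag(wh @ wh @ wh)  # 2x the geometric-mean triangle intensity
    else:
        tri = np.diag(a @ a @ a)  # 2 * E_i
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, tri / denom, 0.0)
    return cc


def global_efficiency(paths: PathLengthMatrix) -> float:
    """Eg = mean of 1/L_ij over ordered pairs; disconnected pairs contribute 0."""
    L = paths.lengths
    n = L.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / L
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def characteristic_path_length(paths: PathLengthMatrix) -> float:
    """Harmonic-mean path length, Lp = 1 / Eg; infinite for an edgeless graph."""
    eg = global_efficiency(paths)
    if eg == 0.0:
        warnings.warn("network fully disconnected; Lp is infinite", stacklevel=2)
        return float("inf")
    return 1.0 / eg


def local_efficiency(net: WeightedNetwork) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced subgraph."""
    w = net.weights
    n = net.n_nodes
    effs = np.zeros(n)
    for i in range(n):
        nb = np.nonzero(w[i])[0]
        if nb.size < 2:
            continue
        sub = WeightedNetwork(weights=np.ascontiguousarray(w[np.ix_(nb, nb)]), atlas=_sub_atlas(nb.size))
        effs[i] = global_efficiency(shortest_paths(sub))
    return float(effs.mean())


_SUB_ATLAS_CACHE: dict[int, "object"] = {}


def _sub_atlas(n: int):
    from .atlas import RegionAtlas

    if n not in _SUB_ATLAS_CACHE:
        _SUB_ATLAS_CACHE[n] = RegionAtlas(labels=tuple(f"n{i}" for i in range(n)))
    return _SUB_ATLAS_CACHE[n]


def betweenness(net: WeightedNetwork, normalized: bool = False) -> NodalMetrics:
    """Nodal betweenness centrality on the weighted network.

    B_nod(i) sums, over unordered pairs {j, k} not containing i, the fraction
    of weighted shortest j-k paths passing through i.  Unnormalized by
    default, matching the raw path-count definition; ``normalized=True``
    divides by (N-1)(N-2)/2.
    """
    g = nx.from_numpy_array(net.weights)
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    bc = nx.betweenness_centrality(g, normalized=normalized, weight="length")
    b = np.array([bc[i] for i in range(net.n_nodes)])
    return NodalMetrics(betweenness=b, degree=net.degrees())


def global_metrics(net: WeightedNetwork) -> GlobalMetrics:
    """Cp, Lp, Eg, Eloc for one network (small-world ratios left NaN)."""
    paths = shortest_paths(net)
    eg = global_efficiency(paths)
    return GlobalMetrics(
        Cp=clustering_coefficient(net),
        Lp=characteristic_path_length(paths) if eg > 0 else float("inf"),
        Eg=eg,
        Eloc=local_efficiency(net),
    )


def nodal_metrics(net: WeightedNetwork, normalized: bool = False) -> NodalMetrics:
    return betweenness(net, normalized=normalized)
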