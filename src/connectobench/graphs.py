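"""Edge filtering schemes and graph metrics.

Turns a dense association matrix into a sparse undirected network using one
of the eight filtering schemes of the pipeline grid (absolute threshold at
0.3/0.5; fixed density 5/10/20%; structural density matching; efficiency
cost optimisation; orthogonal minimum spanning trees) plus a plain MST
baseline, with optional binarisation, and computes the graph metrics the
schemes and the evaluation criteria need.

Conventions: negative weights are zeroed before every filter; path lengths
on weighted graphs use the distance transform d = 1/w; weighted clustering
uses the Onnela geometric-mean formula on weights rescaled by the maximum
weight.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path

__all__ = [
    "FilteredNetwork",
    "GraphMetrics",
    "positive_part",
    "absolute_threshold",
    "proportional_threshold",
    "eco_filter",
    "omst_filter",
    "mst_baseline",
    "binarise",
    "graph_metrics",
    "write_edgelist",
    "FILTER_LABELS",
]

FILTER_LABELS = ("abs_0.3", "abs_0.5", "fd_5", "fd_10", "fd_20", "sdm", "eco", "omst")


@dataclasses.dataclass
class FilteredNetwork:
    """Sparse undirected graph as a dense symmetric adjacency matrix
    (0 = absent edge) plus provenance of the filter that produced it."""

    adjacency: np.ndarray
    binary: bool
    filter: str
    source_measure: str = "unknown"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(a < 0) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be non-negative with zero diagonal")
        if self.binary and not np.all(np.isin(a[a != 0], [1.0])):
            raise ValueError("binary network must have all nonzero entries equal to 1")
        self._distances: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    @property
    def is_empty(self) -> bool:
        return self.n_edges == 0

    def distances(self) -> np.ndarray:
        """Shortest-path distance matrix (cached): hop counts for binary
        graphs, Dijkstra on d = 1/w for weighted graphs; +inf when
        unreachable."""
        if self._distances is None:
            a = self.adjacency
            if self.binary:
                d = shortest_path(csr_array(a), method="D", unweighted=True)
            else:
                lengths = np.zeros_like(a)
                mask = a > 0
                lengths[mask] = 1.0 / a[mask]
                d = shortest_path(csr_array(lengths), method="D")
            self._distances = d
        return self._distances


def _as_weights(obj) -> tuple[np.ndarray, str]:
    """Accept a ConnectivityMatrix or a bare symmetric matrix."""
    if hasattr(obj, "weights"):
        return np.asarray(obj.weights, dtype=float), getattr(obj, "measure", "unknown")
    w = np.asarray(obj, dtype=float)
    return w, "unknown"


def positive_part(matrix) -> np.ndarray:
    """Zero out negative entries (a no-op for mutual information)."""
    w, _ = _as_weights(matrix)
    w = w.copy()
    w[w < 0] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def _ranked_edges(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive upper-triangle edges sorted by descending weight, ties broken
    by lexicographically smallest (i, j) pair for determinism."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = weights[iu, ju]
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def _build(n, ii, jj, ww, filter_label, measure, meta=None) -> FilteredNetwork:
    adj = np.zeros((n, n))
    adj[ii, jj] = ww
    adj[jj, ii] = ww
    return FilteredNetwork(adj, False, filter_label, measure, meta or {})


def absolute_threshold(matrix, tau: float) -> FilteredNetwork:
    """Keep edges with (positive) weight >= tau."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    w, measure = _as_weights(matrix)
    w = positive_part(w)
    adj = np.where(w >= tau, w, 0.0)
    label = f"abs_{tau:g}"
    net = FilteredNetwork(adj, False, label, measure)
    net.meta["empty"] = net.is_empty
    return net


def proportional_threshold(
    matrix, density_target: float, filter_label: str | None = None
) -> FilteredNetwork:
    """Retain the ``round(density_target * N(N-1)/2)`` largest positive
    edges (round half away from zero; cutoff ties broken lexicographically)."""
    if not (0 < density_target <= 1):
        raise ValueError("density_target must lie in (0, 1]")
    w, measure = _as_weights(matrix)
    w = positive_part(w)
    n = w.shape[0]
    m = _round_half_away(density_target * n * (n - 1) / 2)
    ii, jj, ww = _ranked_edges(w)
    meta = {"requested_edges": m}
    if m > len(ww):
        meta["deficient"] = True
        m = len(ww)
    net = _build(n, ii[:m], jj[:m], ww[:m], filter_label or f"fd_{100 * density_target:g}", measure, meta)
    net.meta["empty"] = net.is_empty
    return net


def eco_filter(matrix) -> FilteredNetwork:
    """Efficiency cost optimisation: proportional threshold enforcing mean
    node degree 3 (m = round(3N/2) edges).  Records the achieved objective
    J = (E_g + E_l) / density in ``meta['eco_objective']``."""
    w, measure = _as_weights(matrix)
    n = w.shape[0]
    if n < 3:
        raise ValueError("ECO needs at least 3 nodes")
    m = _round_half_away(3 * n / 2)
    density = m / (n * (n - 1) / 2)
    net = proportional_threshold(w, min(1.0, density), filter_label="eco")
    net.source_measure = measure
    metrics = graph_metrics(net)
    net.meta["eco_objective"] = (
        (metrics.global_efficiency + metrics.mean_local_efficiency) / metrics.density
        if metrics.density > 0
        else np.nan
    )
    return net


def _mst_edges(weights: np.ndarray, available: np.ndarray) -> list[tuple[int, int]]:
    """MST (on distances 1/w) of the sub-multigraph of ``available`` edges;
    assumes the available graph is connected."""
    dist = np.zeros_like(weights)
    mask = available & (weights > 0)
    dist[mask] = 1.0 / weights[mask]
    tree = minimum_spanning_tree(csr_array(dist)).tocoo()
    return [(min(i, j), max(i, j)) for i, j in zip(tree.row, tree.col)]


def _is_connected(adj_mask: np.ndarray) -> bool:
    ncomp, _ = connected_components(csr_array(adj_mask.astype(float)), directed=False)
    return ncomp == 1


def mst_baseline(matrix) -> FilteredNetwork:
    """Single minimum spanning tree on distances d = 1/w: exactly N-1 edges,
    connected, and (being a tree) zero clustering."""
    w, measure = _as_weights(matrix)
    w = positive_part(w)
    if not _is_connected(w > 0):
        raise ValueError("positive-part graph is disconnected; MST undefined")
    edges = _mst_edges(w, np.ones_like(w, dtype=bool))
    ii = np.array([e[0] for e in edges], dtype=int)
    jj = np.array([e[1] for e in edges], dtype=int)
    return _build(w.shape[0], ii, jj, w[ii, jj], "mst_baseline", measure)


def omst_filter(matrix, max_rounds: int | None = None) -> FilteredNetwork:
    """Orthogonal minimum spanning trees.

    Iteratively extracts edge-disjoint MSTs (distances d = 1/w) from the
    positive-part graph and accumulates their union; after each round the
    global cost efficiency GCE = E_g - Cost is evaluated on the union, where
    E_g is the weighted global efficiency and Cost is the ratio of selected
    edge weight to the total positive edge weight.  Returns the union at the
    GCE-maximising round; retained edges keep their original weights.  The
    result is always a single connected component (over the nodes of the
    largest component if the input is disconnected, which is flagged).
    """
    w, measure = _as_weights(matrix)
    w = positive_part(w)
    n = w.shape[0]
    active = np.ones(n, dtype=bool)
    disconnected_input = not _is_connected(w > 0)
    if disconnected_input:
        ncomp, labels = connected_components(csr_array((w > 0).astype(float)), directed=False)
        largest = np.argmax(np.bincount(labels))
        active = labels == largest
        w = np.where(np.outer(active, active), w, 0.0)
    total_weight = w[np.triu_indices(n, 1)].sum()
    if total_weight == 0:
        net = FilteredNetwork(np.zeros((n, n)), False, "omst", measure)
        net.meta.update(empty=True, disconnected_input=disconnected_input)
        return net
    if max_rounds is None:
        max_rounds = max(1, (n - 1) // 2)

    selected = np.zeros_like(w, dtype=bool)
    best_gce = -np.inf
    best_selected = None
    best_round = 0
    for round_no in range(1, max_rounds + 1):
        remaining = (w > 0) & ~selected
        if not _is_connected(remaining[np.ix_(active, active)]):
            break
        for i, j in _mst_edges(w, remaining):
            selected[i, j] = selected[j, i] = True
        union = np.where(selected, w, 0.0)
        net = FilteredNetwork(union, False, "omst", measure)
        gce = _global_efficiency(net.distances()) - union[np.triu_indices(n, 1)].sum() / total_weight
        if gce > best_gce:
            best_gce = gce
            best_selected = selected.copy()
            best_round = round_no
    adj = np.where(best_selected, w, 0.0)
    net = FilteredNetwork(adj, False, "omst", measure)
    net.meta.update(
        empty=net.is_empty,
        disconnected_input=disconnected_input,
        gce=best_gce,
        n_rounds=best_round,
    )
    return net


def binarise(net: FilteredNetwork) -> FilteredNetwork:
    """Set all surviving edges to unity; topology unchanged."""
    adj = (net.adjacency > 0).astype(float)
    return FilteredNetwork(adj, True, net.filter, net.source_measure, dict(net.meta))


def write_edgelist(net: FilteredNetwork, path) -> None:
    """Export as TSV edge list (i, j, weight) with 0-based node indices."""
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    edges = np.column_stack([ii, jj, net.adjacency[ii, jj]])
    np.savetxt(path, edges, delimiter="\t", fmt=("%d", "%d", "%.17g"))


@dataclasses.dataclass(frozen=True)
class GraphMetrics:
    density: float
    global_efficiency: float
    mean_local_efficiency: float
    mean_clustering: float
    characteristic_path_length: float
    n_components: int
    mean_degree: float


def _global_efficiency(distances: np.ndarray) -> float:
    n = distances.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / distances[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def _local_efficiency(net: FilteredNetwork) -> float:
    a = net.adjacency
    n = net.n_nodes
    effs = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(a[v] > 0)
        if nb.size < 2:
            continue
        sub = FilteredNetwork(a[np.ix_(nb, nb)], net.binary, net.filter)
        effs[v] = _global_efficiency(sub.distances())
    return float(effs.mean())


def graph_metrics(net: FilteredNetwork) -> GraphMetrics:
    """Density, efficiencies, clustering, path length, components, degree.

    Unreachable pairs contribute 0 to efficiency and are excluded from the
    characteristic path length.
    """
    a = net.adjacency
    n = net.n_nodes
    m = net.n_edges
    density = 2 * m / (n * (n - 1)) if n > 1 else 0.0
    d = net.distances()
    eg = _global_efficiency(d)
    el = _local_efficiency(net)
    off = d[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    cpl = float(finite.mean()) if finite.size else 0.0
    ncomp, _ = connected_components(csr_array((a > 0).astype(float)), directed=False)
    if m == 0:
        clustering = 0.0
    else:
        g = nx.from_numpy_array(a)
        clustering = float(
            nx.average_clustering(g, weight=None if net.binary else "weight")
        )
    return GraphMetrics(
        density=density,
        global_efficiency=eg,
        mean_local_efficiency=el,
        mean_clustering=clustering,
        characteristic_path_length=cpl,
        n_components=int(ncomp),
        mean_degree=2 * m / n,
    )
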