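"""Network portraits and the Portrait Divergence between two networks.

A network portrait is the matrix B whose entry B[l, k] counts the nodes
that have exactly k nodes at shortest-path distance l; it is a graph
invariant (unchanged under node relabelling).  Row l = 0 always has all
mass at k = 1, because each node is at distance zero only from itself.

The Portrait Divergence between two graphs is the Jensen-Shannon
divergence (base-2 logarithm, so the value lies in [0, 1]) between the
distributions

    P(k, l) = P(k | l) P(l)
            = (B[l, k] / N) * (sum_k' k' B[l, k']) / (sum_c n_c^2)

built from each portrait, where n_c are the connected-component sizes.
Zero divergence means topologically indistinguishable portraits; one means
maximal information loss.  The two graphs need not share node or edge
counts.  For weighted networks, rows index equal-width bins of the pooled
finite shortest-path distances of both graphs (shared support makes the
divergence well defined); the self-distance row is kept as row 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_array
from scipy.special import rel_entr

from .graphs import FilteredNetwork

__all__ = [
    "NetworkPortrait",
    "distance_matrix",
    "portrait",
    "weighted_portrait",
    "portrait_divergence",
    "portrait_distribution",
]

DEFAULT_WEIGHTED_BINS = 50


@dataclasses.dataclass
class NetworkPortrait:
    """Portrait matrix B (rows: distance shell l or distance bin; columns:
    k = 0..N-1) with component sizes for the Eq.-style normalisation."""

    B: np.ndarray
    n_nodes: int
    component_sizes: list[int]

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=np.int64)
        if np.any(self.B < 0):
            raise ValueError("portrait entries must be non-negative counts")
        if not np.all(self.B.sum(axis=1) == self.n_nodes):
            raise ValueError("every portrait row must sum to the node count")


def distance_matrix(net: FilteredNetwork) -> np.ndarray:
    """Shortest-path distances: BFS hop counts for binary networks, Dijkstra
    on d = 1/w for weighted; +inf for unreachable pairs."""
    return net.distances()


def _component_sizes(net: FilteredNetwork) -> list[int]:
    _, labels = connected_components(
        csr_array((net.adjacency > 0).astype(float)), directed=False
    )
    return np.bincount(labels).tolist()


def _rows_to_portrait(per_node_counts: np.ndarray, n: int) -> np.ndarray:
    """per_node_counts[i, l] = number of nodes at shell l from node i;
    returns B with B[l, k] = #nodes whose count at shell l is k."""
    n_rows = per_node_counts.shape[1]
    B = np.zeros((n_rows, n), dtype=np.int64)
    for l in range(n_rows):
        B[l] = np.bincount(per_node_counts[:, l], minlength=n)[:n]
    return B


def portrait(net: FilteredNetwork) -> NetworkPortrait:
    """Binary-network portrait with rows l = 0..L (L = largest finite
    distance).  An empty graph has the single row l = 0."""
    if not net.binary and net.adjacency[net.adjacency > 0].size and not np.all(
        net.adjacency[net.adjacency > 0] == 1.0
    ):
        raise ValueError("portrait() expects a binary network; use weighted_portrait")
    d = net.distances()
    n = net.n_nodes
    finite = np.isfinite(d)
    diameter = int(d[finite].max()) if finite.any() else 0
    counts = np.zeros((n, diameter + 1), dtype=np.intp)
    for i in range(n):
        row = d[i][finite[i]].astype(np.intp)
        counts[i] = np.bincount(row, minlength=diameter + 1)[: diameter + 1]
    return NetworkPortrait(_rows_to_portrait(counts, n), n, _component_sizes(net))


def weighted_portrait(
    net: FilteredNetwork,
    n_bins: int = DEFAULT_WEIGHTED_BINS,
    max_distance: float | None = None,
) -> NetworkPortrait:
    """Weighted-network portrait.

    Row 0 holds the self-distances (every node has exactly one node, itself,
    at distance 0); rows 1..n_bins hold equal-width bins spanning
    (0, max_distance].  ``max_distance`` defaults to the graph's own largest
    finite distance, but callers comparing two graphs must pass the pooled
    maximum so both portraits share one binning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    d = net.distances()
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite_off = np.isfinite(d) & off
    if max_distance is None:
        max_distance = float(d[finite_off].max()) if finite_off.any() else 1.0
    if max_distance <= 0:
        max_distance = 1.0
    counts = np.zeros((n, n_bins + 1), dtype=np.intp)
    counts[:, 0] = 1  # each node at distance 0 from itself
    width = max_distance / n_bins
    for i in range(n):
        vals = d[i][finite_off[i]]
        if vals.size:
            idx = np.minimum(np.ceil(vals / width).astype(np.intp), n_bins)
            idx = np.maximum(idx, 1)
            counts[i, :] += np.bincount(idx, minlength=n_bins + 1)[: n_bins + 1]
    return NetworkPortrait(_rows_to_portrait(counts, n), n, _component_sizes(net))


def portrait_distribution(p: NetworkPortrait) -> np.ndarray:
    """The probability grid P(k, l) of a portrait; sums to 1."""
    B = p.B.astype(float)
    n = p.n_nodes
    shell_mass = (B * np.arange(B.shape[1])[None, :]).sum(axis=1)
    total = float(sum(c * c for c in p.component_sizes))
    # total equals shell_mass.sum() by construction (each node counts the
    # members of its own component, itself included, exactly once)
    return (B / n) * (shell_mass / total)[:, None]


def _pad_to(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    out[: a.shape[0], : a.shape[1]] = a
    return out


def portrait_divergence(
    g1: FilteredNetwork,
    g2: FilteredNetwork,
    n_bins: int = DEFAULT_WEIGHTED_BINS,
) -> float:
    """Jensen-Shannon divergence (log base 2) between the portrait
    distributions of two networks; lies in [0, 1].

    Binary pairs use integer-shell portraits; weighted pairs share one
    equal-width binning over the pooled finite distances of both networks.
    Raises on empty networks (criterion V handles those upstream) and on a
    binary/weighted mismatch.
    """
    if g1.is_empty or g2.is_empty:
        raise ValueError("portrait divergence undefined for empty networks")
    if g1.binary != g2.binary:
        raise ValueError("cannot compare binary with weighted networks")
    if g1.binary:
        p1, p2 = portrait(g1), portrait(g2)
    else:
        pooled_max = 0.0
        for g in (g1, g2):
            d = g.distances()
            off = np.isfinite(d) & ~np.eye(g.n_nodes, dtype=bool)
            if off.any():
                pooled_max = max(pooled_max, float(d[off].max()))
        p1 = weighted_portrait(g1, n_bins=n_bins, max_distance=pooled_max)
        p2 = weighted_portrait(g2, n_bins=n_bins, max_distance=pooled_max)
    P = portrait_distribution(p1)
    Q = portrait_distribution(p2)
    shape = (max(P.shape[0], Q.shape[0]), max(P.shape[1], Q.shape[1]))
    P, Q = _pad_to(P, shape).ravel(), _pad_to(Q, shape).ravel()
    M = (P + Q) / 2.0
    jsd = 0.5 * rel_entr(P, M).sum() + 0.5 * rel_entr(Q, M).sum()
    return float(min(1.0, max(0.0, jsd / np.log(2.0))))
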