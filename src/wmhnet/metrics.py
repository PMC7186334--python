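"""Weighted network measures for structural brain connectomes.

All measures operate on a symmetric, non-negative edge-weight matrix
(typically fiber count x mean FA after thresholding). Shortest-path
distances map each edge weight ``w`` to a length ``1/w`` — the convention
of the Brain Connectivity Toolbox family — so stronger connections are
"closer". Under this convention the characteristic path length Lp is
defined as the inverse of the mean reciprocal distance, which makes
``Lp * Eg == 1`` an exact identity whenever the global efficiency Eg is
positive.

Measures implemented
--------------------
global : density, mean strength, clustering coefficient (Onnela
    geometric-mean form on max-normalized weights), characteristic path
    length, global efficiency, local efficiency (mean nodal Eloc).
nodal : binary clustering coefficient, nodal path length (mean finite
    shortest distance to the other nodes), nodal efficiency, nodal local
    efficiency (global efficiency of the neighbor subgraph).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path


class DisconnectedGraphError(ValueError):
    """Raised when a measure is undefined because no node pair is connected."""


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix with node labels.

    ``weights[i, j] > 0`` iff an edge is present; the diagonal is zero.
    """

    weights: np.ndarray
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {W.shape}")
        if not np.allclose(W, W.T, atol=1e-12):
            i, j = np.unravel_index(np.argmax(np.abs(W - W.T)), W.shape)
            raise ValueError(f"weight matrix not symmetric at ({i}, {j})")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")
        self.weights = W
        if not self.node_names:
            self.node_names = [f"N{k:03d}" for k in range(W.shape[0])]
        if len(self.node_names) != W.shape[0]:
            raise ValueError("node_names length does not match matrix dimension")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class GlobalMetrics:
    density: float
    strength: float
    cp: float
    lp: float
    eg: float
    eloc: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {"density": self.density, "strength": self.strength, "cp": self.cp,
             "lp": self.lp, "eg": self.eg, "eloc": self.eloc})


@dataclass
class NodalMetrics:
    node_names: list[str]
    cp: np.ndarray
    nlp: np.ndarray
    eg: np.ndarray
    eloc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cp": self.cp, "nlp": self.nlp, "eg": self.eg, "eloc": self.eloc},
            index=pd.Index(self.node_names, name="node"))


def _as_weights(graph) -> np.ndarray:
    if isinstance(graph, WeightedGraph):
        return graph.weights
    return WeightedGraph(np.asarray(graph, dtype=float)).weights


def _node_names(graph, n: int) -> list[str]:
    if isinstance(graph, WeightedGraph):
        return list(graph.node_names)
    return [f"N{k:03d}" for k in range(n)]


def shortest_path_matrix(graph) -> np.ndarray:
    """All-pairs shortest distances with edge length ``1/weight``.

    Unreachable pairs get ``+inf``; the diagonal is zero.
    """
    W = _as_weights(graph)
    n = W.shape[0]
    ii, jj = np.nonzero(W)
    lengths = csr_matrix((1.0 / W[ii, jj], (ii, jj)), shape=(n, n))
    D = _csgraph_shortest_path(lengths, method="D", directed=False)
    np.fill_diagonal(D, 0.0)
    return D


def network_density(graph) -> float:
    """Fraction of possible undirected edges that are present."""
    W = _as_weights(graph)
    n = W.shape[0]
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    n_edges = np.count_nonzero(np.triu(W, 1))
    return n_edges / (n * (n - 1) / 2)


def network_strength(graph) -> float:
    """Mean over nodes of the summed incident edge weights."""
    W = _as_weights(graph)
    return float(W.sum(axis=1).mean())


def global_cp(graph) -> float:
    """Network clustering coefficient, geometric-mean (Onnela) form.

    Weights are normalized by the network maximum so the coefficient lies
    in [0, 1]; nodes with degree < 2 contribute 0 to the mean.
    """
    W = _as_weights(graph)
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return 0.0
    cbrt = np.cbrt(W / wmax)
    # t_i counts ordered (j, k) closed triples through i
    t = np.diag(cbrt @ cbrt @ cbrt)
    k = np.count_nonzero(W, axis=1)
    cp_i = np.zeros(n)
    mask = k >= 2
    cp_i[mask] = t[mask] / (k[mask] * (k[mask] - 1))
    return float(cp_i.mean())


def global_eg(graph, _distances: np.ndarray | None = None) -> float:
    """Global efficiency: mean reciprocal shortest distance over ordered pairs."""
    W = _as_weights(graph)
    n = W.shape[0]
    if n < 2:
        return 0.0
    D = shortest_path_matrix(W) if _distances is None else _distances
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_lp(graph, _distances: np.ndarray | None = None) -> float:
    """Characteristic path length: inverse of the mean reciprocal distance.

    Exactly ``1 / global_eg``; raises :class:`DisconnectedGraphError` when
    no pair of nodes is connected.
    """
    eg = global_eg(graph, _distances=_distances)
    if eg == 0:
        raise DisconnectedGraphError("no finite-distance node pairs; Lp undefined")
    return 1.0 / eg


def _neighbor_subgraph_eg(W: np.ndarray, i: int) -> float:
    nbrs = np.nonzero(W[i])[0]
    if nbrs.size < 2:
        return 0.0
    sub = W[np.ix_(nbrs, nbrs)]
    return global_eg(sub)


def global_eloc(graph) -> float:
    """Local efficiency: mean over nodes of the neighbor-subgraph efficiency."""
    W = _as_weights(graph)
    n = W.shape[0]
    if n == 0:
        return 0.0
    return float(np.mean([_neighbor_subgraph_eg(W, i) for i in range(n)]))


def nodal_metrics(graph) -> NodalMetrics:
    """Per-node clustering, path length, efficiency, and local efficiency.

    * ``cp``   — binary clustering on the thresholded topology,
      E_i / (K_i (K_i - 1) / 2); zero for degree < 2.
    * ``nlp``  — mean shortest distance to the other nodes; unreachable
      pairs are excluded from the mean, a fully isolated node gets +inf.
    * ``eg``   — mean reciprocal shortest distance to the other nodes
      (unreachable pairs contribute 0).
    * ``eloc`` — global efficiency of the subgraph induced by the node's
      neighbors (the node itself removed).
    """
    W = _as_weights(graph)
    n = W.shape[0]
    A = (W > 0).astype(int)
    k = A.sum(axis=1)
    D = shortest_path_matrix(W)

    cp = np.zeros(n)
    eloc = np.zeros(n)
    for i in range(n):
        if k[i] >= 2:
            nbrs = np.nonzero(A[i])[0]
            e_i = np.triu(A[np.ix_(nbrs, nbrs)], 1).sum()
            cp[i] = e_i / (k[i] * (k[i] - 1) / 2)
        eloc[i] = _neighbor_subgraph_eg(W, i)

    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    nlp = np.full(n, np.inf)
    counts = finite.sum(axis=1)
    rows = counts > 0
    sums = np.where(finite, D, 0.0).sum(axis=1)
    nlp[rows] = sums[rows] / counts[rows]

    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    neg = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)

    return NodalMetrics(node_names=_node_names(graph, n), cp=cp, nlp=nlp,
                        eg=neg, eloc=eloc)


def global_metrics(graph) -> GlobalMetrics:
    """All six network-level measures in one pass.

    ``lp`` is reported as +inf when the graph has no connected pair.
    """
    W = _as_weights(graph)
    D = shortest_path_matrix(W)
    eg = global_eg(W, _distances=D)
    lp = 1.0 / eg if eg > 0 else np.inf
    return GlobalMetrics(
        density=network_density(W),
        strength=network_strength(W),
        cp=global_cp(W),
        lp=lp,
        eg=eg,
        eloc=global_eloc(W),
    )


def network_summary(graph) -> tuple[GlobalMetrics, NodalMetrics]:
    """Global and nodal measures sharing one distance/subgraph computation.

    The network-level local efficiency is the mean of the nodal values, so
    computing both levels together halves the per-subject cost.
    """
    W = _as_weights(graph)
    nodal = nodal_metrics(W)
    eg = float(nodal.eg.mean())  # the global mean reciprocal distance
    lp = 1.0 / eg if eg > 0 else np.inf
    glob = GlobalMetrics(
        density=network_density(W),
        strength=network_strength(W),
        cp=global_cp(W),
        lp=lp,
        eg=eg,
        eloc=float(nodal.eloc.mean()),
    )
    return glob, nodal
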