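"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's implementation choices: distances
come from a hand-written triple-loop Floyd-Warshall, clustering from
exhaustive triple enumeration, efficiencies from direct evaluation of the
defining sums.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances, edge length = 1/weight, triple loop."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def brute_density(W: np.ndarray) -> float:
    n = W.shape[0]
    edges = sum(1 for i in range(n) for j in range(i + 1, n) if W[i, j] > 0)
    return edges / (n * (n - 1) / 2)


def brute_strength(W: np.ndarray) -> float:
    return float(np.mean([W[i].sum() for i in range(W.shape[0])]))


def brute_global_cp(W: np.ndarray) -> float:
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return 0.0
    c = np.cbrt(W / wmax)
    total = 0.0
    for i in range(n):
        k_i = int(np.count_nonzero(W[i]))
        if k_i < 2:
            continue
        s = 0.0
        for j in range(n):
            for k in range(n):
                if j != k and j != i and k != i:
                    s += c[i, j] * c[i, k] * c[j, k]
        total += s / (k_i * (k_i - 1))
    return total / n


def brute_global_eg(W: np.ndarray, D: np.ndarray | None = None) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    if D is None:
        D = floyd_warshall(W)
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]):
                s += 1.0 / D[i, j]
    return s / (n * (n - 1))


def brute_global_lp(W: np.ndarray) -> float:
    eg = brute_global_eg(W)
    return 1.0 / eg


def _neighbor_eg(W: np.ndarray, i: int) -> float:
    nbrs = [j for j in range(W.shape[0]) if W[i, j] > 0]
    if len(nbrs) < 2:
        return 0.0
    sub = W[np.ix_(nbrs, nbrs)]
    return brute_global_eg(sub)


def brute_global_eloc(W: np.ndarray) -> float:
    n = W.shape[0]
    return float(np.mean([_neighbor_eg(W, i) for i in range(n)]))


def brute_nodal(W: np.ndarray):
    """Per-node (cp, nlp, eg, eloc) by direct evaluation."""
    n = W.shape[0]
    D = floyd_warshall(W)
    cp = np.zeros(n)
    nlp = np.full(n, np.inf)
    neg = np.zeros(n)
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k_i = len(nbrs)
        if k_i >= 2:
            e_i = sum(1 for a in range(k_i) for b in range(a + 1, k_i)
                      if W[nbrs[a], nbrs[b]] > 0)
            cp[i] = e_i / (k_i * (k_i - 1) / 2)
        eloc[i] = _neighbor_eg(W, i)
        finite = [D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j])]
        if finite:
            nlp[i] = sum(finite) / len(finite)
        neg[i] = sum(1.0 / D[i, j] for j in range(n)
                     if j != i and np.isfinite(D[i, j])) / (n - 1)
    return cp, nlp, neg, eloc


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float) -> np.ndarray:
    """Symmetric random weight matrix with roughly the requested density."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.2, 2.0)
    return W
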