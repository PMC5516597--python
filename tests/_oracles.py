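"""Independent brute-force oracles used by the test suite.

Everything here enumerates exhaustively (simple paths, triangles, BH
thresholds) and is deliberately independent of the package's algorithmic
path: slow, obvious, and only usable on tiny inputs.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_simple_paths(W: np.ndarray, s: int, t: int):
    """All simple paths s -> t in an undirected weighted graph, as node lists."""
    R = W.shape[0]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for nxt in range(R):
            if W[last, nxt] > 0 and nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([s])
    return paths


def path_length(W: np.ndarray, path) -> float:
    return sum(1.0 / W[a, b] for a, b in zip(path[:-1], path[1:]))


def brute_shortest_paths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances by exhaustive simple-path enumeration."""
    R = W.shape[0]
    D = np.full((R, R), np.inf)
    np.fill_diagonal(D, 0.0)
    for s in range(R):
        for t in range(s + 1, R):
            lengths = [path_length(W, p) for p in enumerate_simple_paths(W, s, t)]
            if lengths:
                D[s, t] = D[t, s] = min(lengths)
    return D


def brute_betweenness(W: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Normalized betweenness by enumerating all shortest paths with multiplicity."""
    R = W.shape[0]
    b = np.zeros(R)
    for s in range(R):
        for t in range(s + 1, R):
            paths = enumerate_simple_paths(W, s, t)
            if not paths:
                continue
            lengths = np.array([path_length(W, p) for p in paths])
            short = [p for p, L in zip(paths, lengths) if L <= lengths.min() + tol]
            for p in short:
                for v in p[1:-1]:
                    b[v] += 1.0 / len(short)
    return b * 2.0 / ((R - 1) * (R - 2))


def brute_clustering(W: np.ndarray) -> np.ndarray:
    """Per-node geometric-mean weighted clustering by explicit triangle loops."""
    R = W.shape[0]
    wmax = W.max()
    c = np.zeros(R)
    if wmax == 0:
        return c
    Wn = W / wmax
    for i in range(R):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        tri = 0.0
        for j in range(R):
            for h in range(R):
                if j != i and h != i and j != h:
                    tri += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        c[i] = tri / (k * (k - 1))
    return c


def brute_bh(pvals, q):
    """BH rejection set by scanning every candidate threshold k."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            best_k = k
    rejected = np.zeros(m, bool)
    rejected[order[:best_k]] = True
    return rejected


def random_connected_graph(rng: np.random.Generator, R: int, p_edge: float = 0.5):
    """Random connected weighted graph with uniform(0.1, 1) weights."""
    while True:
        W = np.zeros((R, R))
        for i, j in itertools.combinations(range(R), 2):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = rng.uniform(0.1, 1.0)
        # connectivity check by BFS
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in np.flatnonzero(W[v] > 0):
                if u not in seen:
                    seen.add(int(u))
                    frontier.append(int(u))
        if len(seen) == R:
            return W


def simple_regression_t(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form t of the slope in y ~ 1 + x via normal equations."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    b = (xc @ yc) / (xc @ xc)
    a = y.mean() - b * x.mean()
    resid = y - a - b * x
    se = np.sqrt((resid @ resid) / (n - 2) / (xc @ xc))
    return b / se
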