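"""Weighted graph metrics at global, nodal, and edge resolution.

Conventions
-----------
* A weight of exactly 0 means the edge is absent.
* Path-based metrics map weight to length as ``1/w`` (stronger connection =
  shorter path), the standard convention for probabilistic connection
  weights.
* Characteristic path length averages finite distances only; the number of
  unreachable pairs is available from the distance matrix.
* Cost-integrated metrics binarize the graph at each density of an
  equispaced cost grid and average the binary metric across the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .core import ConnectomeStack, WeightedConnectome


def _weights(w) -> np.ndarray:
    if isinstance(w, WeightedConnectome):
        return w.weights
    return np.asarray(w, dtype=float)


def n_possible_edges(R: int) -> int:
    return R * (R - 1) // 2


# ---------------------------------------------------------------------------
# cost and degree

def network_cost(w) -> float:
    """Weighted network density: sum of edge weights over R(R-1)/2.

    Equals the mean nodal degree; a simple estimator of physical wiring cost.
    """
    W = _weights(w)
    R = W.shape[0]
    iu = np.triu_indices(R, 1)
    return float(W[iu].sum() / n_possible_edges(R))


def nodal_degree(w) -> np.ndarray:
    """Average connectivity of each node across its R-1 possible connections."""
    W = _weights(w)
    R = W.shape[0]
    return W.sum(axis=0) / (R - 1)


# ---------------------------------------------------------------------------
# clustering

def weighted_clustering(w) -> tuple[np.ndarray, float]:
    """Per-node weighted clustering coefficient and its global (node-mean) value.

    Geometric-mean-of-triangle-weights formulation on weights scaled by the
    maximum weight; for binary graphs this reduces to the triangle fraction.
    Nodes with binary degree < 2 get 0.
    """
    W = _weights(w)
    R = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(R), 0.0
    cube = np.cbrt(W / wmax)
    triangles = np.diagonal(cube @ cube @ cube)  # 2 * sum of triangle geometric means
    k = (W > 0).sum(axis=0)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c, float(c.mean())


# ---------------------------------------------------------------------------
# shortest paths and derived metrics

def shortest_paths(w) -> np.ndarray:
    """All-pairs shortest-path distances on edge lengths 1/w.

    Absent edges (w == 0) carry no length; unreachable pairs are ``inf``.
    """
    W = _weights(w)
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)
    return _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False)


def characteristic_path_length(
    w,
    normalize: bool = False,
    n_random: int = 100,
    rewires_per_edge: int = 20,
    seed=None,
) -> float:
    """Mean finite shortest-path distance over distinct node pairs.

    With ``normalize=True`` the value is divided by the mean characteristic
    path length of ``n_random`` degree-preserving rewired surrogates.
    """
    W = _weights(w)
    if not np.any(W > 0):
        raise ValueError("characteristic path length undefined for an empty graph")
    L = _mean_finite_distance(shortest_paths(W))
    if not normalize:
        return L
    rng = np.random.default_rng(seed)
    ref = []
    for _ in range(n_random):
        surrogate = random_reference(
            W, rewires_per_edge=rewires_per_edge, seed=rng.integers(2**31)
        )
        ref.append(_mean_finite_distance(shortest_paths(surrogate.weights)))
    return L / float(np.mean(ref))


def _mean_finite_distance(D: np.ndarray) -> float:
    R = D.shape[0]
    off = ~np.eye(R, dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        raise ValueError("no finite distances: graph has no edges")
    return float(D[finite].mean())


def n_unreachable_pairs(w) -> int:
    """Number of unordered node pairs with no connecting path."""
    D = shortest_paths(w)
    iu = np.triu_indices(D.shape[0], 1)
    return int(np.isinf(D[iu]).sum())


def global_efficiency(w) -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/inf = 0)."""
    D = shortest_paths(w)
    R = D.shape[0]
    off = ~np.eye(R, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].mean())


def nodal_efficiency(w) -> np.ndarray:
    """Per-node efficiency: global efficiency of the subgraph of the node's neighbors."""
    W = _weights(w)
    R = W.shape[0]
    eff = np.zeros(R)
    for i in range(R):
        nbrs = np.flatnonzero(W[i] > 0)
        if nbrs.size < 2:
            continue
        eff[i] = global_efficiency(W[np.ix_(nbrs, nbrs)])
    return eff


def betweenness(w) -> np.ndarray:
    """Node betweenness centrality on 1/w lengths, normalized by (R-1)(R-2).

    The fraction of all-pairs shortest paths (with multiplicity, endpoints
    excluded) that pass through each node.
    """
    W = _weights(w)
    R = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(R))
    iu, ju = np.triu_indices(R, 1)
    nz = W[iu, ju] > 0
    G.add_weighted_edges_from(
        zip(iu[nz].tolist(), ju[nz].tolist(), (1.0 / W[iu[nz], ju[nz]]).tolist()),
        weight="length",
    )
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(R)])


# ---------------------------------------------------------------------------
# degree-preserving random reference

def random_reference(w, rewires_per_edge: int = 20, seed=None) -> WeightedConnectome:
    """Degree-preserving randomization by double-edge swaps, weights carried.

    Performs ``rewires_per_edge * n_edges`` successful Maslov--Sneppen swaps
    on the binary topology; each weight travels with its (relabelled) edge,
    so the binary degree sequence, edge count, and weight multiset are all
    preserved exactly.  If no legal swap can be found the input is returned
    unchanged with a warning.
    """
    W = _weights(w).copy()
    R = W.shape[0]
    iu, ju = np.triu_indices(R, 1)
    nz = W[iu, ju] > 0
    edges = list(zip(iu[nz].tolist(), ju[nz].tolist()))
    weights = W[iu[nz], ju[nz]].tolist()
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("random_reference needs at least 2 edges")
    present = set(edges)
    rng = np.random.default_rng(seed)
    target = rewires_per_edge * n_edges
    successes = 0
    attempts = 0
    max_attempts = 100 * target
    while successes < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(n_edges), rng.integers(n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed swap: (a,b),(c,d) -> (a,d),(c,b)
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if a == d or c == b or new1 == new2:
            continue
        if new1 in present or new2 in present:
            continue
        present.discard(edges[e1])
        present.discard(edges[e2])
        present.add(new1)
        present.add(new2)
        edges[e1], edges[e2] = new1, new2
        successes += 1
    if successes < target:
        warnings.warn(
            f"random_reference reached only {successes}/{target} swaps "
            "(no further legal swap found)",
            stacklevel=2,
        )
    out = np.zeros_like(W)
    for (i, j), wt in zip(edges, weights):
        out[i, j] = out[j, i] = wt
    return WeightedConnectome(out, getattr(w, "subject_id", "") + "_rand")


# ---------------------------------------------------------------------------
# binarization over a cost grid, cost-integrated metrics

def binarize_at_cost(w, kappa: float) -> WeightedConnectome:
    """Keep the round(kappa * R(R-1)/2) strongest edges, binarized.

    Ties are broken by (i, j) lexicographic order for determinism.  Zero
    weights are never retained; asking for more edges than exist raises.
    """
    if not 0 < kappa <= 1:
        raise ValueError(f"target cost must lie in (0, 1], got {kappa}")
    W = _weights(w)
    R = W.shape[0]
    k = int(round(kappa * n_possible_edges(R)))
    iu, ju = np.triu_indices(R, 1)
    vals = W[iu, ju]
    nnz = int((vals > 0).sum())
    if k > nnz:
        raise ValueError(
            f"cannot binarize at cost {kappa}: needs {k} edges, graph has {nnz}"
        )
    order = np.lexsort((ju, iu, -vals))[:k]
    out = np.zeros_like(W)
    out[iu[order], ju[order]] = 1.0
    out += out.T
    return WeightedConnectome(out, getattr(w, "subject_id", ""))


@dataclass(frozen=True)
class CostGrid:
    """Ordered cost (density) levels for cost-integrated metrics.

    Bounds run from the minimal non-trivial density 1/(R(R-1)/2) up to the
    largest density attainable by every subject in the sample.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("empty cost grid")
        if np.any(v <= 0) or np.any(v > 1):
            raise ValueError("cost grid values must lie in (0, 1]")
        if np.any(np.diff(v) <= 0):
            raise ValueError("cost grid must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_bounds(cls, R: int, kappa_max: float, n: int = 50) -> "CostGrid":
        lo = 1.0 / n_possible_edges(R)
        if kappa_max <= lo:
            raise ValueError("kappa_max must exceed the single-edge cost")
        return cls(tuple(np.linspace(lo, kappa_max, n)))

    @classmethod
    def from_stack(cls, stack: ConnectomeStack, n: int = 50) -> "CostGrid":
        """Grid up to the smallest maximum binary density common to all subjects."""
        M = n_possible_edges(stack.atlas.R)
        arr = stack.weight_array()
        iu, ju = np.triu_indices(stack.atlas.R, 1)
        nnz = (arr[:, iu, ju] > 0).sum(axis=1)
        kappa_max = float(nnz.min()) / M
        return cls.from_bounds(stack.atlas.R, kappa_max, n)


class CostIntegrated(NamedTuple):
    value: float
    n_excluded: int


def cost_integrated_metric(
    w, metric: Callable[[WeightedConnectome], float], grid: CostGrid
) -> CostIntegrated:
    """Average a global metric over binarized versions of ``w`` at each grid cost.

    Uniform weights over an equispaced grid (equivalent to a normalized
    trapezoid up to endpoint effects).  Grid points where the metric is
    undefined are excluded from the average and counted.
    """
    vals = []
    excluded = 0
    for kappa in grid.values:
        try:
            g = binarize_at_cost(w, kappa)
            vals.append(metric(g))
        except ValueError:
            excluded += 1
    if not vals:
        raise ValueError("metric undefined at every grid cost")
    return CostIntegrated(float(np.mean(vals)), excluded)


# ---------------------------------------------------------------------------
# per-subject metric bundle

@dataclass
class MetricSet:
    """Global and nodal metrics for one subject."""

    subject_id: str
    cost: float
    degree: np.ndarray
    clustering: np.ndarray
    clustering_global: float
    char_path_length: float
    global_efficiency: float
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray

    @property
    def betweenness_global(self) -> float:
        return float(self.betweenness.mean())


def compute_metric_set(w: WeightedConnectome) -> MetricSet:
    """All weighted metrics for one subject (path length unnormalized)."""
    c, c_glob = weighted_clustering(w)
    return MetricSet(
        subject_id=w.subject_id,
        cost=network_cost(w),
        degree=nodal_degree(w),
        clustering=c,
        clustering_global=c_glob,
        char_path_length=characteristic_path_length(w),
        global_efficiency=global_efficiency(w),
        nodal_efficiency=nodal_efficiency(w),
        betweenness=betweenness(w),
    )


def metric_table(stack: ConnectomeStack) -> "pd.DataFrame":
    """Long-format table (subject_id, metric, node, value) for a stack."""
    import pandas as pd

    rows = []
    labels = stack.atlas.labels
    for s in stack.subjects:
        ms = compute_metric_set(s)
        rows.append((s.subject_id, "cost", "global", ms.cost))
        rows.append((s.subject_id, "clustering", "global", ms.clustering_global))
        rows.append((s.subject_id, "char_path_length", "global", ms.char_path_length))
        rows.append((s.subject_id, "global_efficiency", "global", ms.global_efficiency))
        rows.append((s.subject_id, "betweenness", "global", ms.betweenness_global))
        for name, vec in (
            ("degree", ms.degree),
            ("clustering", ms.clustering),
            ("nodal_efficiency", ms.nodal_efficiency),
            ("betweenness", ms.betweenness),
        ):
            for i, lab in enumerate(labels):
                rows.append((s.subject_id, name, lab, float(vec[i])))
    return pd.DataFrame(rows, columns=["subject_id", "metric", "node", "value"])
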