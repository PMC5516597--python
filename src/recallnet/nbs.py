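"""Network-based statistic: cluster inference on edge-level associations.

Per-edge t-statistics for the association between an edge's weight and the
phenotype (with nuisance covariates), thresholded at a cluster-forming value
``T``; connected components of the suprathreshold graph are scored by edge
count, and family-wise-error-corrected p-values come from a permutation null
of the maximal component size.  The default threshold is one-sided
(positive association), matching a cluster-forming tail probability of
about .0063 at ``T = 2.5`` with ~660 residual degrees of freedom; a
two-sided mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats as st

from .core import ConnectomeStack, EdgeMask

#: Cluster-forming threshold presets (primary and supplementary analyses).
THRESHOLD_PRESETS = {"lenient": 2.0, "primary": 2.5, "stringent": 3.0}


def masked_edge_values(stack: ConnectomeStack, mask: EdgeMask):
    """Per-subject values of every retained edge.

    Returns ``(values, (i_idx, j_idx))`` with ``values`` of shape
    (n_subjects, n_edges) in upper-triangle order.
    """
    ei, ej = mask.edge_index()
    arr = stack.weight_array()
    return arr[:, ei, ej], (ei, ej)


@dataclass
class EdgeStatMap:
    """Per-edge t-statistics over a masked edge set."""

    t: np.ndarray
    df: int
    edge_index: tuple[np.ndarray, np.ndarray]
    threshold: float | None = None
    two_sided: bool = False
    degenerate: np.ndarray | None = None  # edges constant across subjects

    @property
    def suprathreshold(self) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("no threshold set on this stat map")
        if self.two_sided:
            return np.abs(self.t) >= self.threshold
        return self.t >= self.threshold


def _residualizer(Z: np.ndarray):
    Q, _ = np.linalg.qr(Z)
    return lambda v: v - Q @ (Q.T @ v)


def edge_t_stats(
    recall: np.ndarray,
    edges: np.ndarray,
    covariates: np.ndarray | None,
    threshold: float | None = None,
    two_sided: bool = False,
    edge_index=None,
) -> EdgeStatMap:
    """OLS t-statistic of each edge's coefficient in recall ~ edge + covariates.

    Computed through residualization on [intercept, covariates] (the
    Frisch--Waugh--Lovell identity), which gives exactly the full-model
    coefficient t.  Residual degrees of freedom are n minus the number of
    design columns (intercept + edge + covariates).  Edges constant across
    subjects get t = 0 with a degeneracy flag; an exact linear fit reports a
    +/-inf sentinel.
    """
    y = np.asarray(recall, dtype=float)
    E = np.atleast_2d(np.asarray(edges, dtype=float))
    if E.shape[0] != y.shape[0]:
        E = E.T
    n, m = E.shape
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient covariate design")
    df = n - Z.shape[1] - 1
    if df < 1:
        raise ValueError("not enough subjects for the requested design")
    resid = _residualizer(Z)
    ry = resid(y)
    RE = resid(E)
    ree = (RE**2).sum(axis=0)
    degenerate = ree <= 1e-12 * max(1.0, float(np.abs(E).max()) ** 2)
    v = RE.T @ ry
    ryy = float(ry @ ry)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = ryy - v**2 / ree
        sse = np.maximum(sse, 0.0)
        t = np.where(
            sse > 1e-12 * max(ryy, 1.0),
            v / np.sqrt(sse * ree / df),
            np.sign(v) * np.inf,
        )
    t = np.where(degenerate, 0.0, t)
    return EdgeStatMap(t, df, edge_index if edge_index is not None else (None, None),
                       threshold, two_sided, degenerate)


# ---------------------------------------------------------------------------
# connected components of the suprathreshold graph

@dataclass
class Component:
    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    p_fwe: float | None = None

    @property
    def size(self) -> int:
        """Component extent = number of edges."""
        return len(self.edges)


def _components_from_edges(ei: np.ndarray, ej: np.ndarray) -> list[Component]:
    """Connected components (by union-find) of an edge list; size = edge count."""
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(ei.tolist(), ej.tolist()):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[tuple[int, int]]] = {}
    for a, b in zip(ei.tolist(), ej.tolist()):
        groups.setdefault(find(a), []).append((a, b))
    comps = []
    for edges in groups.values():
        nodes = sorted({x for e in edges for x in e})
        comps.append(Component(tuple(nodes), tuple(sorted(edges))))
    comps.sort(key=lambda c: -c.size)
    return comps


def suprathreshold_components(statmap: EdgeStatMap, atlas=None) -> list[Component]:
    """Connected components of the suprathreshold edge graph, largest first."""
    supra = statmap.suprathreshold
    ei, ej = statmap.edge_index
    if ei is None:
        raise ValueError("stat map carries no edge index")
    return _components_from_edges(ei[supra], ej[supra])


def _max_component_size(ei: np.ndarray, ej: np.ndarray) -> int:
    if ei.size == 0:
        return 0
    return _components_from_edges(ei, ej)[0].size


# ---------------------------------------------------------------------------
# permutation FWE inference

@dataclass
class NBSResult:
    components: list[Component]
    null_max_sizes: np.ndarray
    n_perm: int
    T: float
    alpha: float
    seed: int | None
    df: int
    t: np.ndarray = field(repr=False, default=None)
    edge_index: tuple = field(repr=False, default=None)

    @property
    def significant(self) -> list[Component]:
        return [c for c in self.components if c.p_fwe is not None and c.p_fwe < self.alpha]


def nbs_fwe(
    recall: np.ndarray,
    edges: np.ndarray,
    covariates: np.ndarray | None,
    edge_index,
    T: float = 2.5,
    n_perm: int = 10000,
    alpha: float = 0.005,
    seed: int | None = None,
    two_sided: bool = False,
    allow_small: bool = False,
) -> NBSResult:
    """Network-based statistic with permutation FWE control on component size.

    The phenotype is residualized on the covariates once, then permuted
    across subjects (covariates stay with their subjects), re-deriving the
    full suprathreshold component map at each permutation and recording the
    maximal component size.  ``p_fwe = (1 + #{null >= observed}) /
    (n_perm + 1)``.
    """
    if n_perm < 100 and not allow_small:
        raise ValueError("n_perm < 100 gives statistically meaningless p-values")
    y = np.asarray(recall, dtype=float)
    E = np.atleast_2d(np.asarray(edges, dtype=float))
    if E.shape[0] != y.shape[0]:
        E = E.T
    n, m = E.shape
    ei, ej = edge_index
    statmap = edge_t_stats(y, E, covariates, threshold=T, two_sided=two_sided,
                           edge_index=(np.asarray(ei), np.asarray(ej)))
    observed = suprathreshold_components(statmap)

    if covariates is None:
        Z = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        Z = np.column_stack([np.ones(n), C])
    resid = _residualizer(Z)
    ry = resid(y)
    RE = resid(E)
    ree = (RE**2).sum(axis=0)
    good = ree > 1e-12 * max(1.0, float(np.abs(E).max()) ** 2)
    df = statmap.df
    ei = np.asarray(ei)
    ej = np.asarray(ej)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    sqrt_df = np.sqrt(df)
    for b in range(n_perm):
        yp = ry[rng.permutation(n)]
        v = RE.T @ yp
        ryy = float(yp @ yp)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt(np.maximum(ree * ryy - v**2, 0.0))
            tb = np.where(denom > 0, v * sqrt_df / denom, np.inf * np.sign(v))
        tb = np.where(good, tb, 0.0)
        supra = (np.abs(tb) >= T) if two_sided else (tb >= T)
        null_max[b] = _max_component_size(ei[supra], ej[supra])

    for comp in observed:
        comp.p_fwe = float((1 + np.sum(null_max >= comp.size)) / (n_perm + 1))
    return NBSResult(observed, null_max, n_perm, T, alpha, seed, df,
                     t=statmap.t, edge_index=(ei, ej))


def t_threshold_p(T: float, df: int) -> float:
    """One-sided upper-tail probability of the central t distribution at T."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(st.t.sf(T, df))


def threshold_for_p(p: float, df: int) -> float:
    """Inverse of :func:`t_threshold_p`: the T giving a one-sided tail of p."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(st.t.isf(p, df))
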