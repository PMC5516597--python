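"""Phenotype-network association statistics.

The inference chain is: residualize the phenotype and the network measures
on nuisance covariates (age, gender, and intracranial volume for network
measures), then test rank associations with Spearman's correlation,
controlling multiplicity with Benjamini--Hochberg FDR inside each level of a
global -> nodal -> edge hierarchy.  Each level is tested only if the level
below rejected its null, which keeps the number of simultaneous hypotheses
small where effects are expected to be diffuse.  A robust bisquare multiple
regression quantifies the joint variance explained by a set of edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from . import metrics as gm
from .core import CohortTable, ConnectomeStack, EdgeMask, apply_mask


# ---------------------------------------------------------------------------
# residualization

def residualize(y: np.ndarray, covariates: np.ndarray | None, add_intercept: bool = True) -> np.ndarray:
    """Ordinary least-squares residuals of ``y`` on a covariate design.

    An intercept column is prepended unless ``add_intercept=False`` (in which
    case the design must already contain one).  The design must be full rank
    with more observations than columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n:
            X = X.T
        if X.shape[0] != n:
            raise ValueError("covariates and y have different lengths")
        if add_intercept:
            X = np.column_stack([np.ones(n), X])
    if n <= X.shape[1]:
        raise ValueError(f"n={n} observations cannot support {X.shape[1]} design columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# Spearman association with percentile-bootstrap CI

@dataclass
class AssociationResult:
    """Spearman association with a 95% percentile bootstrap CI."""

    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    B: int
    seed: int | None = None


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return st.rankdata(a, axis=axis)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    y = y - y.mean(axis=-1, keepdims=True)
    num = (x * y).sum(axis=-1)
    den = np.sqrt((x**2).sum(axis=-1) * (y**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def spearman_assoc(
    x, y, B: int = 2000, seed: int | None = None
) -> AssociationResult:
    """Spearman correlation with t-approximation p-value and bootstrap CI.

    Ranks use average ranking of ties; the two-sided p-value comes from
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.  The CI is the
    2.5/97.5 percentile of ``B`` case-resampled correlations (``B=0`` skips
    the bootstrap and reports a NaN interval).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have the same length")
    if n < 10:
        raise ValueError("spearman_assoc needs n >= 10")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) <= 1e-10 * (1.0 + float(np.abs(v).max())):
            raise ValueError(
                f"Spearman correlation undefined: {name} is (numerically) constant"
            )
    r, p = st.spearmanr(x, y)
    ci_low = ci_high = float("nan")
    if B > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(B, n))
        rx = _rank(x[idx])
        ry = _rank(y[idx])
        boots = _pearson_rows(rx, ry)
        boots = boots[np.isfinite(boots)]
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return AssociationResult(float(r), float(p), float(ci_low), float(ci_high), n, B, seed)


# ---------------------------------------------------------------------------
# Benjamini--Hochberg FDR

@dataclass
class BHResult:
    rejected: np.ndarray          # boolean, original order
    adjusted: np.ndarray          # monotone BH-adjusted p-values
    critical_p: float             # largest rejected raw p (0.0 if none)
    q: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def bh_fdr(pvals, q: float = 0.05) -> BHResult:
    """Benjamini--Hochberg step-up over a family of p-values.

    Rejects the k* smallest p-values where k* = max{k : p_(k) <= k q / m};
    the critical p is p_(k*).  Adjusted p-values use the monotone
    min-forward form.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ranked <= thresh)
    rejected = np.zeros(m, dtype=bool)
    critical = 0.0
    if passing.size:
        k_star = passing[-1]
        rejected[order[: k_star + 1]] = True
        critical = float(ranked[k_star])
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return BHResult(rejected, adjusted, critical, q)


# ---------------------------------------------------------------------------
# hierarchical cascade

#: Names of the global cost-integrated metric family tested alongside cost.
GLOBAL_METRIC_FAMILY = (
    "network_cost",
    "global_efficiency_ci",
    "clustering_ci",
    "char_path_length_ci",
    "betweenness_ci",
)


@dataclass
class HierarchicalResult:
    """Three-level global -> nodal -> edge inference output."""

    q: float
    global_results: dict[str, AssociationResult]
    global_adjusted_p: dict[str, float]
    level1_rejected: bool
    nodal: pd.DataFrame | None = None
    nodal_rejected: list[int] = field(default_factory=list)
    nodal_critical_p: float = 0.0
    edges: pd.DataFrame | None = None
    edge_rejected: list[tuple[int, int]] = field(default_factory=list)
    edge_critical_p: float = 0.0


def _design(cohort: CohortTable, cols: Sequence[str]) -> np.ndarray:
    return np.column_stack([cohort.column(c) for c in cols])


def _safe_assoc(x, y, B, seed) -> AssociationResult:
    """Spearman association, degrading to r=NaN / p=1 for a constant measure.

    A measure that does not vary across subjects carries no evidence either
    way; recording p=1 keeps the test family intact without aborting the
    cascade.
    """
    try:
        return spearman_assoc(x, y, B=B, seed=seed)
    except ValueError:
        return AssociationResult(float("nan"), 1.0, float("nan"), float("nan"),
                                 len(x), B, seed)


def _cost_integrated_globals(
    stack: ConnectomeStack,
    grid: gm.CostGrid,
    n_random: int,
    path_grid_stride: int,
    seed,
) -> dict[str, np.ndarray]:
    """Per-subject cost-integrated global metrics over a common grid.

    The normalized characteristic path length is integrated on a strided
    sub-grid because each grid point requires ``n_random`` degree-preserving
    surrogates; with ``n_random=0`` the unnormalized path length is used.
    """
    rng = np.random.default_rng(seed)
    path_grid = gm.CostGrid(grid.values[::path_grid_stride])
    out = {name: np.empty(len(stack)) for name in GLOBAL_METRIC_FAMILY[1:]}
    for s_idx, subj in enumerate(stack.subjects):
        out["global_efficiency_ci"][s_idx] = gm.cost_integrated_metric(
            subj, gm.global_efficiency, grid
        ).value
        out["clustering_ci"][s_idx] = gm.cost_integrated_metric(
            subj, lambda g: gm.weighted_clustering(g)[1], grid
        ).value
        out["betweenness_ci"][s_idx] = gm.cost_integrated_metric(
            subj, lambda g: float(gm.betweenness(g).mean()), grid
        ).value

        def _cpl(g):
            if n_random > 0:
                return gm.characteristic_path_length(
                    g, normalize=True, n_random=n_random, seed=rng.integers(2**31)
                )
            return gm.characteristic_path_length(g)

        out["char_path_length_ci"][s_idx] = gm.cost_integrated_metric(
            subj, _cpl, path_grid
        ).value
    return out


def hierarchical_cascade(
    stack: ConnectomeStack,
    mask: EdgeMask,
    cohort: CohortTable,
    q: float = 0.05,
    *,
    grid: gm.CostGrid | None = None,
    grid_points: int = 50,
    n_random: int = 100,
    path_grid_stride: int = 5,
    B: int = 0,
    seed: int | None = None,
) -> HierarchicalResult:
    """Global -> nodal -> edge hierarchical FDR inference on recall associations.

    Level 1 tests Spearman(residualized recall, residualized network cost),
    BH-adjusted jointly with the four cost-integrated global metrics
    (efficiency, clustering, normalized path length, betweenness).  Only if
    the cost test is rejected does level 2 test the 82 nodal degrees (BH over
    nodes); only if level 2 rejects does level 3 test every retained edge
    incident to a rejected node (BH over that edge set, each undirected edge
    once).  Recall is residualized on age and gender; network measures
    additionally on intracranial volume.
    """
    cohort = cohort.aligned_to(stack.subject_ids)
    masked = apply_mask(stack, mask)
    rng = np.random.default_rng(seed)

    recall_res = residualize(cohort.column("recall_total"), _design(cohort, ("age", "gender")))
    net_cov = _design(cohort, ("age", "gender", "icv"))

    arr = masked.weight_array()
    R = stack.atlas.R
    iu, ju = np.triu_indices(R, 1)
    cost = arr[:, iu, ju].sum(axis=1) / gm.n_possible_edges(R)

    global_vals: dict[str, np.ndarray] = {"network_cost": cost}
    if grid is None:
        grid = gm.CostGrid.from_stack(masked, n=grid_points)
    global_vals.update(
        _cost_integrated_globals(masked, grid, n_random, path_grid_stride, rng.integers(2**31))
    )

    global_results = {
        name: _safe_assoc(residualize(vals, net_cov), recall_res, B, int(rng.integers(2**31)))
        for name, vals in global_vals.items()
    }
    fam = list(global_results)
    bh1 = bh_fdr([global_results[name].p for name in fam], q)
    global_adj = {name: float(bh1.adjusted[i]) for i, name in enumerate(fam)}
    level1_rejected = global_adj["network_cost"] <= q

    result = HierarchicalResult(
        q=q,
        global_results=global_results,
        global_adjusted_p=global_adj,
        level1_rejected=level1_rejected,
    )
    if not level1_rejected:
        return result

    # level 2: nodal degree
    degree = arr.sum(axis=2) / (R - 1)  # (n, R)
    rows = []
    for i in range(R):
        res = _safe_assoc(residualize(degree[:, i], net_cov), recall_res, B,
                          int(rng.integers(2**31)))
        rows.append((i, stack.atlas.labels[i], res.r, res.p, res.ci_low, res.ci_high))
    nodal = pd.DataFrame(rows, columns=["node", "label", "r", "p", "ci_low", "ci_high"])
    bh2 = bh_fdr(nodal["p"].to_numpy(), q)
    nodal["rejected"] = bh2.rejected
    nodal["p_adjusted"] = bh2.adjusted
    result.nodal = nodal
    result.nodal_rejected = nodal.loc[nodal["rejected"], "node"].tolist()
    result.nodal_critical_p = bh2.critical_p
    if not result.nodal_rejected:
        return result

    # level 3: retained edges incident to rejected nodes, each undirected edge once
    rej = np.zeros(R, dtype=bool)
    rej[result.nodal_rejected] = True
    mi, mj = mask.edge_index()
    sel = rej[mi] | rej[mj]
    ei, ej = mi[sel], mj[sel]
    rows = []
    for a, b in zip(ei.tolist(), ej.tolist()):
        res = _safe_assoc(residualize(arr[:, a, b], net_cov), recall_res, B,
                          int(rng.integers(2**31)))
        rows.append((a, b, stack.atlas.labels[a], stack.atlas.labels[b],
                     res.r, res.p, res.ci_low, res.ci_high))
    edges = pd.DataFrame(
        rows, columns=["node_a", "node_b", "label_a", "label_b", "r", "p", "ci_low", "ci_high"]
    )
    if len(edges):
        bh3 = bh_fdr(edges["p"].to_numpy(), q)
        edges["rejected"] = bh3.rejected
        edges["p_adjusted"] = bh3.adjusted
        result.edge_rejected = [
            (int(a), int(b)) for a, b in edges.loc[edges["rejected"], ["node_a", "node_b"]].itertuples(index=False)
        ]
        result.edge_critical_p = bh3.critical_p
    result.edges = edges
    return result


# ---------------------------------------------------------------------------
# robust bisquare regression

@dataclass
class RobustFit:
    coefficients: np.ndarray      # intercept first
    r_squared: float
    iterations: int
    converged: bool
    c: float
    scale: float


def robust_r2(
    y, X, c: float = 4.685, tol: float = 1e-8, max_iter: int = 100
) -> RobustFit:
    """Iteratively reweighted least squares with Tukey bisquare weights.

    The scale is re-estimated each iteration as MAD/0.6745 of the current
    residuals (MAD about zero, appropriate for residuals of a model with an
    intercept).  ``r_squared = 1 - SSE/SST`` uses the unweighted residuals of
    the converged fit, matching how variance explained is reported for a
    robust linear model.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("robust_r2 needs n > predictors + 1")
    Xd = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("singular design matrix")
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    converged = False
    it = 0
    scale = 0.0
    for it in range(1, max_iter + 1):
        resid = y - Xd @ beta
        scale = np.median(np.abs(resid)) / 0.6745
        if scale == 0:  # perfect fit
            converged = True
            break
        u = resid / (c * scale)
        wgt = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if wgt.sum() == 0:
            break
        sw = np.sqrt(wgt)
        beta_new, *_ = np.linalg.lstsq(Xd * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    resid = y - Xd @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    return RobustFit(beta, min(max(r2, 0.0), 1.0), it, converged, c, float(scale))


# ---------------------------------------------------------------------------
# volumetry control analysis

@dataclass
class VolumeAssociationResult:
    per_node: pd.DataFrame
    rejected: list[int]
    critical_p: float
    mean_volume: AssociationResult


def volume_association(
    cohort: CohortTable,
    atlas,
    q: float = 0.05,
    B: int = 0,
    seed: int | None = None,
) -> VolumeAssociationResult:
    """Grey-matter-volume control analysis.

    Recall is residualized on age and gender; each node's volume (and the
    whole-brain mean volume) on age, gender, and intracranial volume.
    Spearman per node, BH FDR over nodes.
    """
    if not cohort.has_volumes:
        raise ValueError("cohort table has no per-node volume columns")
    rng = np.random.default_rng(seed)
    recall_res = residualize(cohort.column("recall_total"), _design(cohort, ("age", "gender")))
    vol_cov = _design(cohort, ("age", "gender", "icv"))
    vols = cohort.volumes(atlas)
    rows = []
    for i, label in enumerate(atlas.labels):
        res = spearman_assoc(residualize(vols[:, i], vol_cov), recall_res, B=B,
                             seed=int(rng.integers(2**31)))
        rows.append((i, label, res.r, res.p, res.ci_low, res.ci_high))
    per_node = pd.DataFrame(rows, columns=["node", "label", "r", "p", "ci_low", "ci_high"])
    bh = bh_fdr(per_node["p"].to_numpy(), q)
    per_node["rejected"] = bh.rejected
    per_node["p_adjusted"] = bh.adjusted
    mean_res = spearman_assoc(
        residualize(vols.mean(axis=1), vol_cov), recall_res, B=B, seed=int(rng.integers(2**31))
    )
    return VolumeAssociationResult(
        per_node, per_node.loc[per_node["rejected"], "node"].tolist(), bh.critical_p, mean_res
    )


def control_analysis(
    cohort: CohortTable,
    cost: np.ndarray,
    controls: Sequence[str] = ("attention", "working_memory"),
    B: int = 0,
    seed: int | None = None,
) -> dict[str, AssociationResult]:
    """Re-run the cost--recall association with extra control covariates.

    Each control variable is added to both residualization designs (recall:
    age + gender + control; cost: age + gender + ICV + control), one control
    at a time.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for ctrl in controls:
        recall_res = residualize(
            cohort.column("recall_total"), _design(cohort, ("age", "gender", ctrl))
        )
        cost_res = residualize(np.asarray(cost, float), _design(cohort, ("age", "gender", "icv", ctrl)))
        out[ctrl] = spearman_assoc(cost_res, recall_res, B=B, seed=int(rng.integers(2**31)))
    return out
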