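"""Synthetic cohort generator with planted, calibrated effects.

Emulates the data-generating structure the analysis pipeline assumes: a
cohort of subjects, each with a symmetric 82 x 82 matrix of connection
probabilities derived from one shared lognormal template, a latent memory
trait driving valence-split binomial recall counts, a global multiplicative
subject factor inducing a target rank correlation between network cost and
recall, an optional set of planted effect edges calibrated to a target
jointly-explained variance, nuisance covariates (age, gender, intracranial
volume) loading on both sides, and per-node grey-matter volumes that are
null with respect to recall unless an effect is planted.

Calibration
-----------
The cost--recall rank correlation survives a chain of monotone transforms
but is attenuated by binomial discretization of recall, so the Gaussian
copula parameter is found by root-finding on a cached million-sample
Monte-Carlo map of the full transform chain.  The planted edge loading is
found from the closed-form R^2 of the linear model on the simulation scale
(lognormal moment formulas), using the same Monte-Carlo estimate of the
latent-trait/recall correlation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
import scipy.stats as st

from .atlas import NodeAtlas
from .core import (
    CohortTable,
    ConnectomeStack,
    WeightedConnectome,
    VOLUME_PREFIX,
    read_connectome_stack,
    write_connectome_stack,
)
from .metrics import n_possible_edges

#: Fixed seed of the calibration Monte-Carlo map.  A design constant, not a
#: tunable: cohorts must be reproducible from (config, seed) alone, so the
#: calibration map cannot depend on the cohort seed.
_CALIBRATION_SEED = 20170523
_CALIBRATION_N = 1_000_000
_CALIBRATION_CACHE: dict = {}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Defaults reproduce the study conditions the pipeline targets: 664
    subjects, 82 nodes, 24 pictures per valence with emotional material
    remembered better than neutral, a small positive global cost--recall
    rank correlation, and null grey-matter volumes.
    """

    n: int = 664
    R: int = 82
    seed: int = 0
    # template
    template_density: float = 0.30
    weight_median: float = 0.02
    weight_sigma: float = 1.0
    # planted global effect
    rho_global: float = 0.102
    sigma_subject: float = 0.12    # sd of the log subject scale factor
    sigma_edge: float = 0.25       # sd of per-edge multiplicative log-noise
    # planted edge effects
    effect_edges: tuple[tuple[int, int], ...] | None = None
    n_effect_edges: int = 0
    edge_r2_target: float = 0.0
    gamma_edge: float = 0.16       # log-scale loading of effect edges on the edge factor
    # recall model
    n_pictures_per_valence: int = 24
    valence_means: tuple[float, float, float] = (5.5, 3.5, 4.5)  # neg, neut, pos
    memory_slope: float = 0.35     # logit slope on the latent memory trait
    recall_age: float = -0.05      # logit loadings on standardized covariates
    recall_gender: float = 0.15
    # covariates
    age_mean: float = 22.85
    age_sd: float = 3.37
    female_frac: float = 0.595
    icv_mean: float = 1.55e6       # mm^3
    icv_sd: float = 1.3e5
    icv_gender: float = -1.2e5     # shift for gender = 1 (female)
    cost_age: float = -0.02        # log-cost loadings on standardized covariates
    cost_gender: float = 0.0
    cost_icv: float = 0.05
    # grey-matter volumes
    with_volumes: bool = True
    vol_sigma: float = 0.10
    vol_icv: float = 0.10
    vol_age: float = -0.05
    volume_effect: tuple[tuple[int, float], ...] | None = None  # (node, target rho)

    def __post_init__(self) -> None:
        if not 0 <= self.template_density <= 1:
            raise ValueError("template_density must lie in [0, 1]")
        if not abs(self.rho_global) < 1:
            raise ValueError("|rho_global| must be < 1")
        if not 0 <= self.edge_r2_target < 1:
            raise ValueError("edge_r2_target must lie in [0, 1)")
        neg, neut, pos = self.valence_means
        if not (neg > neut and pos > neut):
            raise ValueError("valence means must order negative > neutral and positive > neutral")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticCohort:
    stack: ConnectomeStack
    cohort: CohortTable
    truth: dict
    config: SyntheticConfig
    template: WeightedConnectome


# ---------------------------------------------------------------------------
# template

def make_template(
    R: int,
    template_density: float,
    weight_median: float = 0.02,
    weight_sigma: float = 1.0,
    seed=None,
) -> WeightedConnectome:
    """Connected symmetric template with lognormal weights clipped to (0, 1].

    A random spanning tree guarantees connectivity; remaining edges are
    sampled uniformly from the complement until exactly
    ``round(density * R(R-1)/2)`` edges exist.
    """
    rng = np.random.default_rng(seed)
    M = n_possible_edges(R)
    n_edges = int(round(template_density * M))
    if n_edges < R - 1:
        raise ValueError(
            f"density {template_density} gives {n_edges} edges; a connected "
            f"graph on {R} nodes needs at least {R - 1}"
        )
    order = rng.permutation(R)
    chosen = set()
    for k in range(1, R):
        a = order[k]
        b = order[rng.integers(k)]
        chosen.add((min(a, b), max(a, b)))
    iu, ju = np.triu_indices(R, 1)
    all_edges = list(zip(iu.tolist(), ju.tolist()))
    remaining = [e for e in all_edges if e not in chosen]
    extra = rng.choice(len(remaining), size=n_edges - len(chosen), replace=False)
    for k in extra:
        chosen.add(remaining[k])
    W = np.zeros((R, R))
    edges = sorted(chosen)
    wts = np.minimum(
        np.exp(rng.normal(np.log(weight_median), weight_sigma, len(edges))), 1.0
    )
    for (i, j), w in zip(edges, wts):
        W[i, j] = W[j, i] = w
    return WeightedConnectome(W, "template")


def template_for_config(cfg: SyntheticConfig) -> WeightedConnectome:
    """The template a given config will use, without simulating subjects.

    Useful for choosing planted effect edges against the realized topology.
    """
    ss = np.random.SeedSequence(cfg.seed)
    return make_template(
        cfg.R, cfg.template_density, cfg.weight_median, cfg.weight_sigma,
        np.random.default_rng(ss.spawn(4)[0]),
    )


def choose_effect_edges(
    template: WeightedConnectome, k: int, seed=None, min_weight: float = 0.01
) -> tuple[tuple[int, int], ...]:
    """Pick ``k`` template edges to carry a planted effect.

    Restricted to edges with template weight >= ``min_weight`` so planted
    effects sit on connections that survive population-level filtering.
    """
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(template.R, 1)
    ok = template.weights[iu, ju] >= min_weight
    cand = np.flatnonzero(ok)
    if cand.size < k:
        raise ValueError(f"template has only {cand.size} edges above {min_weight}")
    sel = rng.choice(cand, size=k, replace=False)
    return tuple(sorted((int(iu[s]), int(ju[s])) for s in sel))


# ---------------------------------------------------------------------------
# subject-level draws (shared by the simulator and the calibration map)

def _draw_subjects(rng: np.random.Generator, cfg: SyntheticConfig, n: int) -> dict:
    m = rng.standard_normal(n)
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    gender = (rng.random(n) < cfg.female_frac).astype(int)
    icv = cfg.icv_mean + cfg.icv_gender * (gender - cfg.female_frac) + rng.normal(0, cfg.icv_sd, n)
    p = cfg.female_frac
    age_std = (age - cfg.age_mean) / cfg.age_sd
    gender_std = (gender - p) / np.sqrt(p * (1 - p))
    icv_sd_total = np.sqrt(cfg.icv_sd**2 + cfg.icv_gender**2 * p * (1 - p))
    icv_std = (icv - cfg.icv_mean) / icv_sd_total
    shift = cfg.memory_slope * m + cfg.recall_age * age_std + cfg.recall_gender * gender_std
    counts = {}
    for name, mean in zip(("negative", "neutral", "positive"), cfg.valence_means):
        alpha = logit(mean / cfg.n_pictures_per_valence)
        counts[name] = rng.binomial(cfg.n_pictures_per_valence, expit(alpha + shift))
    return dict(
        m=m, age=age, gender=gender, icv=icv,
        age_std=age_std, gender_std=gender_std, icv_std=icv_std,
        recall_negative=counts["negative"], recall_neutral=counts["neutral"],
        recall_positive=counts["positive"],
        recall_total=counts["negative"] + counts["neutral"] + counts["positive"],
    )


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return y - Xd @ beta


def _cov_log_variance(cfg: SyntheticConfig) -> float:
    return cfg.cost_age**2 + cfg.cost_gender**2 + cfg.cost_icv**2


def _calibration_key(cfg: SyntheticConfig) -> tuple:
    return (
        max(cfg.n, 50), cfg.n_pictures_per_valence, cfg.valence_means, cfg.memory_slope,
        cfg.recall_age, cfg.recall_gender, cfg.sigma_subject,
        cfg.cost_age, cfg.cost_gender, cfg.cost_icv, cfg.female_frac,
    )


def _block_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Within-block OLS residuals; y is (B, n), X is (B, n, p) incl. intercept."""
    beta = np.einsum("bpn,bn->bp", np.linalg.pinv(X), y)
    return y - np.einsum("bni,bi->bn", X, beta)


def _calibration_map(cfg: SyntheticConfig) -> dict:
    """Cached million-subject Monte-Carlo map of the cost--recall transform chain.

    The map estimates the quantity the analysis actually reports: the
    *expected within-cohort* Spearman correlation at the configured sample
    size, i.e. residualization and ranking happen inside blocks of n
    subjects and the per-block correlations are averaged.  (The population
    rank correlation differs from this at order 1/n.)
    """
    key = _calibration_key(cfg)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    # block size floors at 50: the finite-n estimand correction only matters
    # for realistically sized cohorts, and tiny blocks cannot support the
    # covariate design
    block_n = max(cfg.n, 50)
    n_blocks = max(_CALIBRATION_N // block_n, 2)
    N = n_blocks * block_n
    s = _draw_subjects(rng, cfg, N)
    u_z = rng.standard_normal(N)
    ones = np.ones(N)
    shape = (n_blocks, block_n)
    X_recall = np.stack(
        [ones, s["age_std"], s["gender_std"]], axis=-1
    ).reshape(n_blocks, block_n, 3)
    X_net = np.stack(
        [ones, s["age_std"], s["gender_std"], s["icv_std"]], axis=-1
    ).reshape(n_blocks, block_n, 4)
    recall_res = _block_residuals(
        s["recall_total"].astype(float).reshape(shape), X_recall
    )
    recall_rank = st.rankdata(recall_res, axis=1)
    rr_c = recall_rank - recall_rank.mean(axis=1, keepdims=True)
    rr_norm = np.sqrt((rr_c**2).sum(axis=1))
    lam = float(np.corrcoef(recall_res.ravel(), s["m"])[0, 1])
    covload = (
        cfg.cost_age * s["age_std"]
        + cfg.cost_gender * s["gender_std"]
        + cfg.cost_icv * s["icv_std"]
    )

    def spearman_at(rho_c: float) -> float:
        z = rho_c * s["m"] + np.sqrt(1.0 - rho_c**2) * u_z
        cost = np.exp(cfg.sigma_subject * z + covload)
        cost_res = _block_residuals(cost.reshape(shape), X_net)
        rc = st.rankdata(cost_res, axis=1)
        rc_c = rc - rc.mean(axis=1, keepdims=True)
        r_blocks = (rc_c * rr_c).sum(axis=1) / (
            np.sqrt((rc_c**2).sum(axis=1)) * rr_norm
        )
        return float(r_blocks.mean())

    out = dict(lam=lam, spearman_at=spearman_at, m=s["m"],
               recall_res=recall_res.ravel(), covload=covload)
    _CALIBRATION_CACHE[key] = out
    return out


def calibrate_global_copula(cfg: SyntheticConfig) -> tuple[float, float]:
    """Copula parameter hitting the target cost--recall Spearman correlation.

    Returns ``(rho_c, lam)`` where ``lam`` is the Pearson correlation between
    residualized recall and the latent memory trait.  Raises with the
    achievable bound if the target is out of reach at the configured noise.
    """
    cal = _calibration_map(cfg)
    target = cfg.rho_global
    if target == 0.0:
        return 0.0, cal["lam"]
    hi = cal["spearman_at"](0.999)
    lo = cal["spearman_at"](-0.999)
    if not lo < target < hi:
        raise ValueError(
            f"rho_global={target} unreachable; achievable range is "
            f"[{lo:.3f}, {hi:.3f}] at the configured noise levels"
        )
    rho_c = brentq(lambda r: cal["spearman_at"](r) - target, -0.999, 0.999, xtol=1e-4)
    return float(rho_c), cal["lam"]


def _solve_edge_loading(cfg: SyntheticConfig, rho_c: float, lam: float, k: int,
                        target_pop: float) -> float:
    """Closed-form (lognormal moments, equicorrelated set) root-find for the
    edge-factor/memory correlation giving a population R^2 of ``target_pop``."""
    var_cov = _cov_log_variance(cfg)
    s2 = cfg.sigma_subject**2 + cfg.gamma_edge**2 + cfg.sigma_edge**2 + var_cov

    def r2_of(rho_gm: float) -> float:
        c_m = cfg.sigma_subject * rho_c + cfg.gamma_edge * rho_gm
        cov_off = (
            cfg.sigma_subject**2
            + cfg.gamma_edge**2
            + 2 * cfg.sigma_subject * cfg.gamma_edge * rho_c * rho_gm
            + var_cov
        )
        rho_off = (np.exp(cov_off) - 1.0) / (np.exp(s2) - 1.0)
        c = lam * c_m / np.sqrt(np.exp(s2) - 1.0)
        return k * c**2 / (1.0 + (k - 1) * rho_off)

    hi = r2_of(0.999)
    if target_pop >= hi:
        raise ValueError(
            f"edge_r2_target={cfg.edge_r2_target} unreachable; at the "
            f"configured loadings the population maximum is {hi:.4f}"
        )
    return float(brentq(lambda r: r2_of(r) - target_pop, 0.0, 0.999, xtol=1e-6))


def _expected_robust_gap(cfg: SyntheticConfig, rho_c: float, rho_gm: float,
                         k: int, n_rep: int = 40) -> float:
    """Expected (OLS - robust) in-sample R^2 gap at the configured n and k.

    The bisquare coefficients are not the SSE minimizer, so the unweighted
    R^2 the robust fit reports sits slightly below the OLS value; the gap
    depends on the phenotype's (non-Gaussian) residual distribution and is
    estimated here by simulating k-edge fits directly on the simulation
    scale, with the fixed calibration seed.
    """
    from .association import robust_r2 as _robust_r2

    cal = _calibration_map(cfg)
    rng = np.random.default_rng(_CALIBRATION_SEED + 1)
    m_all, y_all, covload_all = cal["m"], cal["recall_res"], cal["covload"]
    gaps = []
    for _ in range(n_rep):
        idx = rng.integers(0, m_all.size, cfg.n)
        m = m_all[idx]
        y = y_all[idx]
        z = rho_c * m + np.sqrt(1 - rho_c**2) * rng.standard_normal(cfg.n)
        g = rho_gm * m + np.sqrt(1 - rho_gm**2) * rng.standard_normal(cfg.n)
        eps = rng.normal(0.0, cfg.sigma_edge, (cfg.n, k))
        X = np.exp(
            (cfg.sigma_subject * z + covload_all[idx] + cfg.gamma_edge * g)[:, None]
            + eps
        )
        fit = _robust_r2(y, X)
        Xd = np.column_stack([np.ones(cfg.n), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        ols = 1.0 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum())
        gaps.append(ols - fit.r_squared)
    return float(np.mean(gaps))


def calibrate_edge_loading(cfg: SyntheticConfig, rho_c: float, lam: float, k: int) -> float:
    """Edge-factor/memory correlation hitting the target joint edge R^2.

    Closed form on the simulation scale: each planted edge is lognormal with
    a shared memory-linked factor, so the population R^2 of the k-edge
    linear model follows from lognormal moment formulas for an
    equicorrelated predictor set.  ``edge_r2_target`` is the *in-sample*
    R^2 the robust k-predictor fit reports at the configured cohort size, so
    two finite-sample effects are folded into the solved-for population
    value: the usual degrees-of-freedom inflation
    (R^2_pop = 1 - (1 - target)(n-1)/(n-k-1)) and the small systematic gap
    between the robust and the OLS in-sample R^2 (Monte-Carlo estimate).
    """
    if cfg.edge_r2_target == 0.0 or k == 0:
        return 0.0
    if cfg.n <= k + 2:
        raise ValueError("cohort too small for the requested number of effect edges")
    cache_key = (_calibration_key(cfg), round(rho_c, 6), k, cfg.n,
                 cfg.gamma_edge, cfg.sigma_edge, cfg.edge_r2_target)
    if cache_key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[cache_key]

    def deflate(target_ols: float) -> float:
        target_pop = 1.0 - (1.0 - target_ols) * (cfg.n - 1) / (cfg.n - k - 1)
        if target_pop <= 0:
            raise ValueError(
                f"edge_r2_target={cfg.edge_r2_target} is below the chance "
                f"in-sample R^2 of a {k}-predictor fit at n={cfg.n}"
            )
        return target_pop

    rho_gm = _solve_edge_loading(cfg, rho_c, lam, k, deflate(cfg.edge_r2_target))
    gap = _expected_robust_gap(cfg, rho_c, rho_gm, k)
    out = _solve_edge_loading(cfg, rho_c, lam, k, deflate(cfg.edge_r2_target + gap))
    _CALIBRATION_CACHE[cache_key] = out
    return out


# ---------------------------------------------------------------------------
# cohort simulation

def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one full synthetic cohort (stack + phenotypes + planted truth)."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_template, rng_subjects, rng_edges, rng_vol = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    atlas = NodeAtlas.desikan_killiany() if cfg.R == 82 else NodeAtlas.generic(cfg.R)
    template = make_template(
        cfg.R, cfg.template_density, cfg.weight_median, cfg.weight_sigma, rng_template
    )
    effect_edges = cfg.effect_edges
    if effect_edges is None and cfg.n_effect_edges > 0:
        effect_edges = choose_effect_edges(template, cfg.n_effect_edges, rng_template)
    effect_edges = tuple(effect_edges or ())
    iu, ju = np.triu_indices(cfg.R, 1)
    tvals = template.weights[iu, ju]
    nz = tvals > 0
    ti, tj, tw = iu[nz], ju[nz], tvals[nz]
    edge_pos = {(int(a), int(b)): idx for idx, (a, b) in enumerate(zip(ti, tj))}
    for e in effect_edges:
        if tuple(e) not in edge_pos:
            raise ValueError(f"effect edge {e} is not a template edge")

    rho_c, lam = calibrate_global_copula(cfg)
    rho_gm = calibrate_edge_loading(cfg, rho_c, lam, len(effect_edges))

    n = cfg.n
    s = _draw_subjects(rng_subjects, cfg, n)
    u_z = rng_subjects.standard_normal(n)
    u_g = rng_subjects.standard_normal(n)
    z = rho_c * s["m"] + np.sqrt(1.0 - rho_c**2) * u_z
    g = rho_gm * s["m"] + np.sqrt(1.0 - rho_gm**2) * u_g
    covload = (
        cfg.cost_age * s["age_std"]
        + cfg.cost_gender * s["gender_std"]
        + cfg.cost_icv * s["icv_std"]
    )
    subject_factor = np.exp(cfg.sigma_subject * z + covload)

    eps = rng_edges.normal(0.0, cfg.sigma_edge, size=(n, tw.size))
    w = tw[None, :] * subject_factor[:, None] * np.exp(eps)
    if effect_edges:
        pos = np.array([edge_pos[tuple(e)] for e in effect_edges])
        w[:, pos] *= np.exp(cfg.gamma_edge * g)[:, None]
    np.minimum(w, 1.0, out=w)
    arr = np.zeros((n, cfg.R, cfg.R))
    arr[:, ti, tj] = w
    arr[:, tj, ti] = w

    ids = [f"S{i + 1:04d}" for i in range(n)]
    stack = ConnectomeStack.from_array(arr, ids, atlas)

    data = {
        "subject_id": ids,
        "recall_total": s["recall_total"],
        "recall_negative": s["recall_negative"],
        "recall_neutral": s["recall_neutral"],
        "recall_positive": s["recall_positive"],
        "attention": np.clip(rng_subjects.normal(0.97, 0.02, n), 0, 1),
        "working_memory": rng_subjects.normal(-0.08, 0.06, n),
        "age": s["age"],
        "gender": s["gender"],
        "icv": s["icv"],
    }
    if cfg.with_volumes:
        base = np.exp(rng_vol.normal(np.log(5000.0), 0.4, cfg.R))
        eta = rng_vol.normal(0.0, 1.0, size=(n, cfg.R))
        logv = (
            np.log(base)[None, :]
            + cfg.vol_icv * s["icv_std"][:, None]
            + cfg.vol_age * s["age_std"][:, None]
            + cfg.vol_sigma * eta
        )
        if cfg.volume_effect:
            for node, rho_t in cfg.volume_effect:
                rho_vm = rho_t / lam
                if not abs(rho_vm) < 1:
                    raise ValueError(
                        f"volume effect rho={rho_t} unreachable (max {lam:.3f})"
                    )
                d = cfg.vol_sigma * rho_vm / np.sqrt(1.0 - rho_vm**2)
                logv[:, node] += d * s["m"]
        vols = np.exp(logv)
        for i, label in enumerate(atlas.labels):
            data[f"{VOLUME_PREFIX}{label}"] = vols[:, i]
    cohort = CohortTable(pd.DataFrame(data))

    truth = {
        "rho_copula": rho_c,
        "rho_edge_factor": rho_gm,
        "lambda_recall_memory": lam,
        "effect_edges": [list(e) for e in effect_edges],
        "gamma_edge": cfg.gamma_edge,
        "memory": s["m"].tolist(),
        "subject_scale": subject_factor.tolist(),
    }
    return SyntheticCohort(stack, cohort, truth, cfg, template)


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(cohort: SyntheticCohort, path) -> None:
    """Emit the on-disk formats the pipeline reads, plus the planted truth."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_connectome_stack(cohort.stack, path / "matrices")
    cohort.stack.atlas.to_tsv(path / "atlas.tsv")
    cohort.cohort.write(path / "cohort.csv")
    cfg = dataclasses.asdict(cohort.config)
    (path / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")
    (path / "truth.json").write_text(
        json.dumps(cohort.truth, indent=1, sort_keys=True) + "\n"
    )


def read_fixture(path) -> tuple[ConnectomeStack, CohortTable, dict, SyntheticConfig]:
    path = Path(path)
    atlas = NodeAtlas.from_tsv(path / "atlas.tsv")
    stack = read_connectome_stack(path / "matrices", atlas)
    cohort = CohortTable.read(path / "cohort.csv")
    truth = json.loads((path / "truth.json").read_text())
    raw = json.loads((path / "config.json").read_text())
    for key in ("effect_edges", "volume_effect"):
        if raw.get(key) is not None:
            raw[key] = tuple(tuple(e) for e in raw[key])
    raw["valence_means"] = tuple(raw["valence_means"])
    cfg = SyntheticConfig(**raw)
    return stack, cohort, truth, cfg
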