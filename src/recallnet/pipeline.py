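"""End-to-end orchestration: mask -> metrics -> cascade -> NBS -> volumetry.

Stages run in the fixed order of the analysis design; levels of the
hierarchical cascade that are gated on a non-rejected lower level are never
evaluated, and the resulting report notes where inference stopped.  All
randomness flows from a single seed recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    control_analysis,
    hierarchical_cascade,
    residualize,
    robust_r2,
    volume_association,
)
from .atlas import NodeAtlas
from .core import CohortTable, ConnectomeStack, apply_mask, population_edge_mask, read_connectome_stack
from .metrics import n_possible_edges
from .nbs import masked_edge_values, nbs_fwe

log = logging.getLogger("recallnet")


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run (defaults = study analysis)."""

    matrices: str = ""
    atlas: str = ""
    cohort: str = ""
    out: str = "recallnet_out"
    q: float = 0.05                    # FDR level per cascade level
    floor: float = 0.01                # population edge-exclusion floor
    nbs_T: float = 2.5                 # cluster-forming threshold
    nbs_n_perm: int = 10000
    nbs_alpha: float = 0.005
    nbs_two_sided: bool = False
    bootstrap_B: int = 2000
    grid_points: int = 50
    n_random: int = 100                # surrogates for normalized path length
    path_grid_stride: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _stage(name: str, **params):
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(
    config: PipelineConfig,
    stack: ConnectomeStack | None = None,
    cohort: CohortTable | None = None,
) -> Path:
    """Run every stage and write TSV reports plus a JSON run manifest.

    ``stack``/``cohort`` may be passed in memory; otherwise they are read
    from the configured paths.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    rng = np.random.default_rng(config.seed)
    try:
        if stack is None:
            atlas = NodeAtlas.from_tsv(config.atlas)
            stack = read_connectome_stack(config.matrices, atlas)
        if cohort is None:
            cohort = CohortTable.read(config.cohort)
        cohort = cohort.aligned_to(stack.subject_ids)
        atlas = stack.atlas

        _stage("mask", floor=config.floor, n_subjects=len(stack))
        mask = population_edge_mask(stack, config.floor)
        np.savetxt(out / "edge_mask.tsv", mask.retained.astype(int), fmt="%d", delimiter="\t")
        masked = apply_mask(stack, mask)

        _stage("cascade", q=config.q, grid_points=config.grid_points, n_random=config.n_random)
        cascade = hierarchical_cascade(
            stack, mask, cohort, config.q,
            grid_points=config.grid_points, n_random=config.n_random,
            path_grid_stride=config.path_grid_stride,
            B=config.bootstrap_B, seed=int(rng.integers(2**31)),
        )
        glob = pd.DataFrame(
            [
                (name, res.r, res.p, cascade.global_adjusted_p[name], res.ci_low, res.ci_high)
                for name, res in cascade.global_results.items()
            ],
            columns=["metric", "r", "p_nominal", "p_fdr", "ci_low", "ci_high"],
        )
        glob.to_csv(out / "global_tests.tsv", sep="\t", index=False)
        if cascade.nodal is not None:
            cascade.nodal.to_csv(out / "nodal_tests.tsv", sep="\t", index=False)
        if cascade.edges is not None:
            cascade.edges.to_csv(out / "edge_tests.tsv", sep="\t", index=False)
        stopped_at = (
            "edge" if cascade.edge_rejected
            else "nodal" if cascade.nodal_rejected
            else "global (cascade stopped at level 1)" if not cascade.level1_rejected
            else "nodal (no node rejected)"
        )
        _stage("cascade_result", level1_rejected=cascade.level1_rejected,
               n_nodes=len(cascade.nodal_rejected), n_edges=len(cascade.edge_rejected),
               stopped_at=repr(stopped_at))

        _stage("control", controls="attention,working_memory")
        iu, ju = np.triu_indices(atlas.R, 1)
        cost = masked.weight_array()[:, iu, ju].sum(axis=1) / n_possible_edges(atlas.R)
        controls = control_analysis(cohort, cost, B=config.bootstrap_B,
                                    seed=int(rng.integers(2**31)))
        pd.DataFrame(
            [(k, v.r, v.p, v.ci_low, v.ci_high) for k, v in controls.items()],
            columns=["control", "r", "p_nominal", "ci_low", "ci_high"],
        ).to_csv(out / "control_tests.tsv", sep="\t", index=False)

        _stage("nbs", T=config.nbs_T, n_perm=config.nbs_n_perm, alpha=config.nbs_alpha)
        edges, edge_index = masked_edge_values(masked, mask)
        covs = np.column_stack(
            [cohort.column("age"), cohort.column("gender"), cohort.column("icv")]
        )
        nbs = nbs_fwe(
            cohort.column("recall_total"), edges, covs, edge_index,
            T=config.nbs_T, n_perm=config.nbs_n_perm, alpha=config.nbs_alpha,
            two_sided=config.nbs_two_sided, seed=int(rng.integers(2**31)),
        )
        pd.DataFrame(
            [
                (ci, len(c.nodes), c.size, c.p_fwe)
                for ci, c in enumerate(nbs.components)
            ],
            columns=["component", "n_nodes", "n_edges", "p_fwe"],
        ).to_csv(out / "nbs_components.tsv", sep="\t", index=False)
        tmap = dict(zip(zip(nbs.edge_index[0].tolist(), nbs.edge_index[1].tolist()), nbs.t))
        for ci, comp in enumerate(nbs.components):
            pd.DataFrame(
                [
                    (atlas.labels[a], atlas.labels[b], tmap[(a, b)])
                    for a, b in comp.edges
                ],
                columns=["node_a", "node_b", "t"],
            ).to_csv(out / f"nbs_component_{ci}_edges.tsv", sep="\t", index=False)

        if cohort.has_volumes:
            _stage("volumetry", q=config.q)
            vol = volume_association(cohort, atlas, config.q, B=0,
                                     seed=int(rng.integers(2**31)))
            vol.per_node.to_csv(out / "volumetry.tsv", sep="\t", index=False)
            _stage("volumetry_result", n_rejected=len(vol.rejected),
                   mean_volume_r=round(vol.mean_volume.r, 4))

        robust_report = {"n_edges": 0}
        if cascade.edge_rejected:
            _stage("robust_fit", n_edges=len(cascade.edge_rejected))
            recall_res = residualize(
                cohort.column("recall_total"),
                np.column_stack([cohort.column("age"), cohort.column("gender")]),
            )
            arr = masked.weight_array()
            X = np.column_stack([arr[:, a, b] for a, b in cascade.edge_rejected])
            fit = robust_r2(recall_res, X)
            robust_report = {
                "n_edges": len(cascade.edge_rejected),
                "r_squared": fit.r_squared,
                "converged": fit.converged,
                "iterations": fit.iterations,
            }
            pd.DataFrame([robust_report]).to_csv(out / "robust_fit.tsv", sep="\t", index=False)

        manifest = {
            "config": dataclasses.asdict(config),
            "versions": {
                "recallnet": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "n_subjects": len(stack),
            "n_retained_edges": mask.n_retained,
            "cascade": {
                "level1_rejected": bool(cascade.level1_rejected),
                "nodal_rejected": [int(i) for i in cascade.nodal_rejected],
                "nodal_critical_p": cascade.nodal_critical_p,
                "edge_rejected": [[int(a), int(b)] for a, b in cascade.edge_rejected],
                "edge_critical_p": cascade.edge_critical_p,
                "stopped_at": stopped_at,
            },
            "nbs": {
                "n_components": len(nbs.components),
                "significant": [
                    {"n_nodes": len(c.nodes), "n_edges": c.size, "p_fwe": c.p_fwe}
                    for c in nbs.significant
                ],
            },
            "robust_fit": robust_report,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        _stage("done", out=str(out))
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
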