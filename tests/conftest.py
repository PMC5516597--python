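import numpy as np
import pytest

from recallnet.atlas import NodeAtlas
from recallnet.core import ConnectomeStack, WeightedConnectome
from recallnet.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_connectome(rng, R=82, density=0.4, subject_id="S") -> WeightedConnectome:
    iu, ju = np.triu_indices(R, 1)
    W = np.zeros((R, R))
    on = rng.random(iu.size) < density
    W[iu[on], ju[on]] = rng.uniform(0.0, 1.0, on.sum())
    W += W.T
    return WeightedConnectome(W, subject_id)


@pytest.fixture
def small_stack(rng):
    atlas = NodeAtlas.generic(12)
    subs = [random_connectome(rng, 12, 0.5, f"S{i}") for i in range(6)]
    return ConnectomeStack(subs, atlas)


#: Small, fast study conditions used by cascade/pipeline tests; the full-size
#: defaults are exercised by the acceptance suite.
SMALL_COHORT_KW = dict(n=160, R=20, template_density=0.35)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a strong global + edge effect concentrated on 5 nodes."""
    cfg = SyntheticConfig(
        seed=42, rho_global=0.45, edge_r2_target=0.30, gamma_edge=0.45,
        **SMALL_COHORT_KW,
    )
    cohort = simulate_cohort(_with_nodal_effect(cfg, nodes=(2, 5, 8, 11, 14)))
    return cohort


@pytest.fixture(scope="session")
def null_cohort():
    cfg = SyntheticConfig(seed=7, rho_global=0.0, edge_r2_target=0.0, **SMALL_COHORT_KW)
    return simulate_cohort(cfg)


def _with_nodal_effect(cfg: SyntheticConfig, nodes):
    """Plant effect edges on every template edge incident to the given nodes."""
    from recallnet.synthetic import template_for_config

    template = template_for_config(cfg)
    iu, ju = np.triu_indices(cfg.R, 1)
    nz = template.weights[iu, ju] > 0
    nodeset = set(nodes)
    edges = tuple(
        (int(a), int(b))
        for a, b in zip(iu[nz], ju[nz])
        if (int(a) in nodeset) ^ (int(b) in nodeset)  # one endpoint per edge
    )
    return cfg.replace(effect_edges=edges)
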