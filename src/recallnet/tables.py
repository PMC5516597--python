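"""Published summary-statistic tables from the original 664-subject study.

The raw cohort behind the original analysis is not publicly deposited, but
its printed per-node and per-edge association tables are.  They serve here
as worked-example inputs for bookkeeping operations (nominal screens,
within-set edge counts, FDR adjustment of the global metric family) and as
the reference surface the re-implementation is checked against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .association import bh_fdr
from .atlas import canonical_key


def _read(name: str) -> pd.DataFrame:
    with resources.files("recallnet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def nodal_associations() -> pd.DataFrame:
    """Per-node degree and grey-matter-volume associations with recall.

    Columns: node, r_degree, p_degree, r_volume, p_volume (82 rows).
    """
    return _read("reference_nodal_associations.tsv")


def fdr_nodes() -> pd.DataFrame:
    """The seven nodes whose degree passed within-level FDR (q < .05)."""
    return _read("reference_fdr_nodes.tsv")


def fdr_edges() -> pd.DataFrame:
    """The 22 edges that passed edge-level FDR (q < .05)."""
    return _read("reference_fdr_edges.tsv")


def global_tests() -> pd.DataFrame:
    """Global family: network cost + four cost-integrated metrics (r, p)."""
    return _read("reference_global_tests.tsv")


def count_nominal_nodes(alpha: float = 0.05) -> int:
    """Number of nodes whose degree association is nominally significant."""
    return int((nodal_associations()["p_degree"] < alpha).sum())


def count_edges_within_fdr_nodes() -> int:
    """FDR edges whose *both* endpoints are FDR nodes."""
    nodes = {canonical_key(n) for n in fdr_nodes()["node"]}
    edges = fdr_edges()
    both = edges.apply(
        lambda row: canonical_key(row["node_a"]) in nodes
        and canonical_key(row["node_b"]) in nodes,
        axis=1,
    )
    return int(both.sum())


def global_family_adjusted_p() -> dict[str, float]:
    """BH adjustment over the five-test global metric family."""
    df = global_tests()
    res = bh_fdr(df["p"].to_numpy(), q=0.05)
    return dict(zip(df["metric"], (float(x) for x in res.adjusted)))
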