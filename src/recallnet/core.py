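"""Data model and I/O for weighted connectomes, cohorts, and edge masks.

A subject's structural connectome is an undirected weighted graph on the
atlas nodes; weights are tractography-derived connection probabilities in
[0, 1], stored as a full symmetric matrix with a zero diagonal.  Edge-level
bookkeeping always iterates the strict upper triangle, the single source of
truth per undirected edge.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import NodeAtlas

#: Column prefix for optional per-node grey-matter volume columns.
VOLUME_PREFIX = "vol_"

_PHENOTYPE_COLUMNS = (
    "subject_id", "recall_total", "recall_negative", "recall_neutral",
    "recall_positive", "attention", "working_memory", "age", "gender", "icv",
)


def _validate_weights(w: np.ndarray, label: str = "connectome") -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{label}: weight matrix must be square, got {w.shape}")
    if not np.issubdtype(w.dtype, np.number):
        raise ValueError(f"{label}: non-numeric weights")
    if not np.all(np.isfinite(w)):
        raise ValueError(f"{label}: non-finite weight")
    if np.any(w < 0):
        raise ValueError(f"{label}: negative weight")
    if np.any(w > 1):
        raise ValueError(f"{label}: weight above 1")
    if np.any(np.diag(w) != 0):
        raise ValueError(f"{label}: diagonal must be zero")
    if not np.array_equal(w, w.T):
        raise ValueError(f"{label}: matrix is not symmetric (symmetrization is explicit)")


@dataclass
class WeightedConnectome:
    """One subject's symmetric connection-probability matrix."""

    weights: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        _validate_weights(self.weights, f"subject {self.subject_id or '<anon>'}")

    @property
    def R(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "WeightedConnectome":
        return WeightedConnectome(self.weights.copy(), self.subject_id)


def symmetrize(directed: np.ndarray, subject_id: str = "") -> WeightedConnectome:
    """Average the directed probabilities p_ij and p_ji into one undirected weight.

    The diagonal is forced to zero.  Inputs must be square and non-negative;
    values are clipped nowhere, so out-of-range averages raise.
    """
    p = np.asarray(directed, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"symmetrize expects a square matrix, got {p.shape}")
    if np.any(p < 0):
        raise ValueError("symmetrize expects non-negative probabilities")
    w = 0.5 * (p + p.T)
    np.fill_diagonal(w, 0.0)
    return WeightedConnectome(w, subject_id)


@dataclass
class ConnectomeStack:
    """Ordered collection of subject connectomes sharing one atlas."""

    subjects: list[WeightedConnectome]
    atlas: NodeAtlas

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject IDs must be unique")
        for s in self.subjects:
            if s.R != self.atlas.R:
                raise ValueError(
                    f"subject {s.subject_id}: matrix is {s.R}x{s.R} "
                    f"but atlas has {self.atlas.R} nodes"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def weight_array(self) -> np.ndarray:
        """All matrices stacked into an (n, R, R) array."""
        return np.stack([s.weights for s in self.subjects])

    @classmethod
    def from_array(
        cls, weights: np.ndarray, subject_ids: Sequence[str], atlas: NodeAtlas
    ) -> "ConnectomeStack":
        if len(subject_ids) != weights.shape[0]:
            raise ValueError("one subject ID per matrix required")
        subjects = [
            WeightedConnectome(weights[i], str(subject_ids[i]))
            for i in range(weights.shape[0])
        ]
        return cls(subjects, atlas)


@dataclass
class EdgeMask:
    """Population-level boolean mask of retained undirected edges."""

    retained: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.retained, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mask must be square")
        if np.any(np.diag(m)):
            raise ValueError("mask diagonal must be False")
        if not np.array_equal(m, m.T):
            raise ValueError("mask must be symmetric")
        self.retained = m

    @property
    def R(self) -> int:
        return self.retained.shape[0]

    @property
    def n_retained(self) -> int:
        """Number of retained undirected edges (counted above the diagonal)."""
        return int(np.triu(self.retained, 1).sum())

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) indices of retained edges, i < j."""
        iu, ju = np.triu_indices(self.R, 1)
        keep = self.retained[iu, ju]
        return iu[keep], ju[keep]


def population_edge_mask(stack: ConnectomeStack, floor: float = 0.01) -> EdgeMask:
    """Retain edge (i, j) iff mean + 2 sd of its weight across subjects >= floor.

    The criterion screens out connections whose population distribution sits
    almost entirely below a minimal connection probability; it is applied
    identically to every subject.  The standard deviation uses the n-1
    (sample) denominator.
    """
    if len(stack) < 2:
        raise ValueError("population_edge_mask needs at least 2 subjects")
    arr = stack.weight_array()
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    retained = (mean + 2.0 * sd) >= floor
    np.fill_diagonal(retained, False)
    return EdgeMask(retained)


def apply_mask(stack: ConnectomeStack, mask: EdgeMask) -> ConnectomeStack:
    """Zero out excluded edges in every subject; zero weight = absent edge."""
    if mask.R != stack.atlas.R:
        raise ValueError("mask dimension does not match atlas")
    arr = stack.weight_array() * mask.retained
    return ConnectomeStack.from_array(arr, stack.subject_ids, stack.atlas)


# ---------------------------------------------------------------------------
# cohort table

@dataclass
class CohortTable:
    """Per-subject phenotypes and covariates.

    Required columns: subject_id, recall_total, age, gender, icv.  Optional:
    recall_negative/neutral/positive (must sum to recall_total when present),
    attention (0-back accuracy), working_memory (2-back minus 0-back
    accuracy), and per-node grey-matter volumes as ``vol_<label>`` columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "recall_total", "age", "gender", "icv"):
            if col not in df.columns:
                raise ValueError(f"cohort table misses required column {col!r}")
        if df["subject_id"].duplicated().any():
            raise ValueError("duplicate subject IDs in cohort table")
        splits = [c for c in ("recall_negative", "recall_neutral", "recall_positive")
                  if c in df.columns]
        if len(splits) == 3:
            total = df[splits].sum(axis=1)
            if not np.array_equal(total.to_numpy(), df["recall_total"].to_numpy()):
                raise ValueError("valence splits do not sum to recall_total")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].astype(str).tolist()

    def column(self, name: str) -> np.ndarray:
        col = self.data[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            raise ValueError(f"cohort column {name!r} has missing values")
        return col

    @property
    def has_volumes(self) -> bool:
        return any(c.startswith(VOLUME_PREFIX) for c in self.data.columns)

    def volumes(self, atlas: NodeAtlas) -> np.ndarray:
        """Per-node grey-matter volumes as an (n, R) array in atlas order."""
        cols = []
        for label in atlas.labels:
            col = f"{VOLUME_PREFIX}{label}"
            if col not in self.data.columns:
                raise ValueError(f"cohort table misses volume column {col!r}")
            cols.append(self.data[col].to_numpy(dtype=float))
        vols = np.column_stack(cols)
        if np.any(~np.isfinite(vols)):
            raise ValueError("volume columns contain missing values")
        return vols

    def aligned_to(self, subject_ids: Iterable[str]) -> "CohortTable":
        """Reorder rows to match a stack's subject order; missing IDs raise."""
        ids = list(subject_ids)
        df = self.data.set_index(self.data["subject_id"].astype(str), drop=False)
        missing = [s for s in ids if s not in df.index]
        if missing:
            raise ValueError(f"cohort table misses subjects: {missing[:5]}")
        return CohortTable(df.loc[ids].reset_index(drop=True))

    @classmethod
    def read(cls, path) -> "CohortTable":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        return cls(pd.read_csv(path, sep=sep))

    def write(self, path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        self.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# matrix file I/O

def read_connectome_stack(path, atlas: NodeAtlas) -> ConnectomeStack:
    """Read a directory of per-subject R x R matrix TSVs (file stem = subject ID).

    Matrices must already be symmetric: symmetrization of raw directed
    probabilities is an explicit step (:func:`symmetrize`), never silent.
    """
    path = Path(path)
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv matrix files under {path}")
    subjects = []
    for f in files:
        try:
            w = np.loadtxt(f, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{f.name}: non-numeric cell ({exc})") from None
        if w.shape != (atlas.R, atlas.R):
            raise ValueError(
                f"{f.name}: expected {atlas.R}x{atlas.R} matrix, got {w.shape}"
            )
        subjects.append(WeightedConnectome(w, f.stem))
    return ConnectomeStack(subjects, atlas)


def write_connectome_stack(stack: ConnectomeStack, path) -> None:
    """Write one ``<subject_id>.tsv`` per subject with full float precision."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for s in stack.subjects:
        np.savetxt(path / f"{s.subject_id}.tsv", s.weights, delimiter="\t", fmt="%.17g")
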