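"""Node atlases for whole-brain structural networks.

The default parcellation combines the 34 Desikan--Killiany cortical gyral
regions per hemisphere with 7 subcortical grey-matter structures per
hemisphere, yielding 82 network nodes.  The atlas fixes the canonical node
ordering used by every connectivity matrix in a study.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

#: Desikan--Killiany cortical gyral labels (34 per hemisphere).
DESIKAN_KILLIANY_CORTICAL = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

#: Subcortical grey-matter structures (7 per hemisphere).
SUBCORTICAL = (
    "Thalamus-Proper", "Caudate", "Putamen", "Pallidum", "Hippocampus",
    "Amygdala", "Accumbens-area",
)


def canonical_key(label: str) -> str:
    """Reduce a region label to lowercase alphanumerics for matching.

    Published tables spell regions inconsistently ("Left Accumbens area",
    "Left accumbens-area", "Left-Accumbens-area"); this key makes them
    comparable.
    """
    return re.sub(r"[^a-z0-9]", "", label.lower())


@dataclass(frozen=True)
class NodeAtlas:
    """Ordered list of network nodes with hemisphere and tissue class.

    The label order is the canonical node index: row/column ``i`` of every
    connectivity matrix refers to ``labels[i]``.
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    tissue_class: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.hemisphere) != n or len(self.tissue_class) != n:
            raise ValueError("labels, hemisphere and tissue_class must have equal length")
        if len(set(self.labels)) != n:
            raise ValueError("atlas labels must be unique")
        bad = set(self.hemisphere) - {"left", "right"}
        if bad:
            raise ValueError(f"hemisphere entries must be left/right, got {bad}")
        bad = set(self.tissue_class) - {"cortical", "subcortical"}
        if bad:
            raise ValueError(f"tissue_class entries must be cortical/subcortical, got {bad}")
        object.__setattr__(
            self, "_index", {canonical_key(l): i for i, l in enumerate(self.labels)}
        )

    @property
    def R(self) -> int:
        """Number of nodes."""
        return len(self.labels)

    def index(self, label: str) -> int:
        """Node index for a label (spelling-insensitive)."""
        key = canonical_key(label)
        if key not in self._index:
            raise KeyError(f"unknown region label: {label!r}")
        return self._index[key]

    @classmethod
    def desikan_killiany(cls) -> "NodeAtlas":
        """The default 82-node atlas: 68 cortical + 14 subcortical regions."""
        labels, hemis, tissue = [], [], []
        for hemi in ("Left", "Right"):
            for name in DESIKAN_KILLIANY_CORTICAL:
                labels.append(f"{hemi}-{name}")
                hemis.append(hemi.lower())
                tissue.append("cortical")
        for hemi in ("Left", "Right"):
            for name in SUBCORTICAL:
                labels.append(f"{hemi}-{name}")
                hemis.append(hemi.lower())
                tissue.append("subcortical")
        return cls(tuple(labels), tuple(hemis), tuple(tissue))

    @classmethod
    def generic(cls, R: int) -> "NodeAtlas":
        """Anonymous atlas of ``R`` nodes, for simulations at non-default sizes."""
        if R < 2:
            raise ValueError("an atlas needs at least 2 nodes")
        half = R // 2
        labels = tuple(f"node{i:03d}" for i in range(R))
        hemis = tuple("left" if i < half else "right" for i in range(R))
        return cls(labels, hemis, ("cortical",) * R)

    @classmethod
    def from_tsv(cls, path) -> "NodeAtlas":
        df = pd.read_csv(path, sep="\t")
        missing = {"label", "hemisphere", "tissue_class"} - set(df.columns)
        if missing:
            raise ValueError(f"atlas table misses columns: {sorted(missing)}")
        return cls(
            tuple(df["label"].astype(str)),
            tuple(df["hemisphere"].astype(str)),
            tuple(df["tissue_class"].astype(str)),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "label": self.labels,
                "hemisphere": self.hemisphere,
                "tissue_class": self.tissue_class,
            }
        ).to_csv(path, sep="\t", index=False)
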