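"""Compare extracted signatures to a reference catalog.

Matching is by cosine similarity, which for non-negative 96-channel
distributions lies in [0, 1]. The catalog (e.g. COSMIC v2, 96 x 30) is a
TSV whose first column holds the channel labels and whose header row
names the signatures. For heatmap-style presentation the catalog columns
can be ordered by average-linkage hierarchical clustering on the
1 - cosine distance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .channels import CHANNEL_LABELS
from .errors import ConfigurationError, DataError


def cosine_similarity(a, b) -> float:
    """Cosine similarity a.b / (|a||b|), clipped into [0, 1] for
    non-negative inputs (clipping only absorbs rounding)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ConfigurationError(f"vector length mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclasses.dataclass
class ReferenceCatalog:
    """A named set of reference signatures (96 x M, columns sum to 1)."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.matrix.index) != list(CHANNEL_LABELS):
            raise DataError("catalog rows must follow the 96-channel catalog order")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = sums.index[~np.isclose(sums, 1.0, atol=1e-6)].tolist()
            raise DataError(f"catalog columns must sum to 1; offending: {bad}")
        if (self.matrix.to_numpy() < 0).any():
            raise DataError("catalog entries must be non-negative")

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(matrix=df)

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="channel")


@dataclasses.dataclass
class MatchResult:
    """Similarity of K extracted signatures against an M-column catalog."""

    similarity: pd.DataFrame  # K x M in [0, 1]
    best_match: list[tuple[str, float]]  # per extracted signature
    catalog_order: list[str]  # clustering leaf order of the catalog

    def best_for(self, signature: str) -> tuple[str, float]:
        return self.best_match[list(self.similarity.index).index(signature)]


def match_to_catalog(W: pd.DataFrame, catalog: ReferenceCatalog) -> MatchResult:
    """Full K x M cosine-similarity matrix plus per-signature best match.

    Ties on the row maximum go to the earlier catalog column.
    """
    if list(W.index) != list(catalog.matrix.index):
        raise DataError("extracted signatures and catalog have misaligned channel labels")
    Wm = W.to_numpy(dtype=float)
    Cm = catalog.matrix.to_numpy(dtype=float)
    wn = np.linalg.norm(Wm, axis=0)
    cn = np.linalg.norm(Cm, axis=0)
    if (wn == 0).any() or (cn == 0).any():
        raise DataError("cosine similarity undefined for a zero signature column")
    sim = np.clip((Wm.T @ Cm) / np.outer(wn, cn), 0.0, 1.0)
    sim_df = pd.DataFrame(sim, index=list(W.columns), columns=catalog.names)
    best = []
    for i in range(sim.shape[0]):
        j = int(np.argmax(sim[i]))  # argmax takes the first maximum: tie -> earlier column
        best.append((catalog.names[j], float(sim[i, j])))
    order = cluster_catalog(catalog)[0] if len(catalog) >= 2 else list(catalog.names)
    return MatchResult(similarity=sim_df, best_match=best, catalog_order=order)


def cluster_catalog(catalog: ReferenceCatalog) -> tuple[list[str], np.ndarray | None]:
    """Average-linkage hierarchical clustering of the catalog columns.

    Distance is 1 - cosine similarity. Returns the leaf order (for
    heatmap axes) and the scipy linkage matrix of merge heights; a
    single-column catalog returns its trivial ordering with no tree.
    """
    names = catalog.names
    if len(names) < 2:
        return list(names), None
    C = catalog.matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(C, axis=0)
    sim = np.clip((C.T @ C) / np.outer(norms, norms), 0.0, 1.0)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # exact symmetry for squareform
    Z = linkage(squareform(dist, checks=False), method="average")
    order = [names[i] for i in leaves_list(Z)]
    return order, Z
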