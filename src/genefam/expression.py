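"""Expression profiling: RPKM normalization and hierarchical clustering.

Mirrors the classic Cluster-3.0-style workflow for RNA-seq gene-family
heatmaps: reads/kilobase/million normalization, correlation distance
(1 - Pearson) between gene profiles, agglomerative linkage, and a k-group
cut of the dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import ExpressionMatrix

DISTANCES = ("pearson", "euclidean")
LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class Dendrogram:
    """A merge sequence over gene ids (scipy linkage encoding)."""

    ids: tuple[str, ...]
    linkage_matrix: np.ndarray
    distance: str
    linkage: str

    def __post_init__(self) -> None:
        if self.linkage_matrix.shape != (len(self.ids) - 1, 4):
            raise ValueError("linkage matrix shape does not match id count")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def rpkm_normalize(
    counts: ExpressionMatrix,
    gene_lengths_bp: Mapping[str, float],
    library_sizes: Mapping[str, float],
) -> ExpressionMatrix:
    """Reads/kilobase/million: count / (length/1e3) / (library/1e6)."""
    if counts.state != "raw_counts":
        raise ValueError(f"expected raw counts, got state {counts.state!r}")
    missing = [g for g in counts.genes if g not in gene_lengths_bp]
    if missing:
        raise ValueError(f"missing gene length for {missing[:5]}")
    lengths = pd.Series({g: float(gene_lengths_bp[g]) for g in counts.genes})
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libs = pd.Series({c: float(library_sizes[c]) for c in counts.conditions})
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    vals = counts.values.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)
    return ExpressionMatrix(values=vals, state="rpkm")


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1); offered for heatmap scaling, off by default upstream."""
    return ExpressionMatrix(values=np.log2(m.values + 1.0), state="log2")


def expressed_filter(m: ExpressionMatrix, min_value: float = 0.0) -> list[str]:
    """Genes with a value strictly above ``min_value`` in >= 1 condition."""
    mask = (m.values > min_value).any(axis=1)
    return [g for g, keep in zip(m.genes, mask) if keep]


def _distance_matrix(m: ExpressionMatrix, distance: str) -> np.ndarray:
    x = m.values.to_numpy(dtype=float)
    if distance == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))
    if distance == "pearson":
        sd = x.std(axis=1)
        constant = np.flatnonzero(sd == 0)
        if constant.size:
            raise ValueError(
                f"constant expression row(s) under pearson distance: "
                f"{[m.genes[i] for i in constant[:5]]}"
            )
        d = 1.0 - np.corrcoef(x)
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, None)
    raise ValueError(f"unknown distance {distance!r}")


def hierarchical_cluster(
    m: ExpressionMatrix,
    distance: str = "pearson",
    linkage_method: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of gene expression profiles."""
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage_method not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage_method!r}")
    if len(m.genes) < 2:
        raise ValueError("clustering needs at least 2 genes")
    d = _distance_matrix(m, distance)
    z = linkage(squareform(d, checks=False), method=linkage_method)
    return Dendrogram(
        ids=tuple(m.genes), linkage_matrix=z,
        distance=distance, linkage=linkage_method,
    )


def cut_clusters(d: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into exactly k groups.

    Group labels are integers 1..k assigned in order of first member
    appearance along the input gene order.
    """
    n = len(d.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = fcluster(d.linkage_matrix, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        raise ValueError(
            f"dendrogram ties prevent a cut into exactly {k} groups "
            f"(got {len(set(raw))})"
        )
    relabel: dict[int, int] = {}
    out = {}
    for gene, lab in zip(d.ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[gene] = relabel[lab]
    return out


def ordered_matrix(m: ExpressionMatrix, d: Dendrogram) -> ExpressionMatrix:
    """Reorder rows into dendrogram leaf order (heat-map ready)."""
    from scipy.cluster.hierarchy import leaves_list

    order = leaves_list(d.linkage_matrix)
    vals = m.values.loc[[d.ids[i] for i in order]]
    return ExpressionMatrix(values=vals, state=m.state)
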