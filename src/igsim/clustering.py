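"""Hierarchical clustering of the similarity matrix.

The matrix is clustered on distances (100 - sim) with a chosen agglomeration
method; the resulting merge tree fixes the row/column order of all outputs
and is cut at ``100 - threshold`` to assign species and genus clusters.  The
tree is used ONLY for ordering and cutting — it is not a phylogeny and is
never rendered as one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from igsim.similarity import SimilarityMatrix

#: Agglomeration methods offered, mapped to scipy linkage names.
AGGLOMERATION_METHODS: dict[str, str] = {
    "complete": "complete",
    "single": "single",
    "average": "average",
    "ward": "ward",
    "ward.D2": "ward",
    "mcquitty": "weighted",
    "weighted": "weighted",
    "centroid": "centroid",
    "median": "median",
}

DEFAULT_METHOD = "complete"


@dataclass
class Dendrogram:
    """Agglomerative merge tree plus the leaf order it induces."""

    linkage: np.ndarray
    ids: list[str]
    leaf_order: list[str]
    method: str


@dataclass
class ClusterTable:
    """Per-genome species/genus cluster labels and the thresholds used."""

    assignments: pd.DataFrame  # columns: genome_id, species_cluster, genus_cluster
    species_threshold: float
    genus_threshold: float

    def cluster_of(self, genome_id: str, level: str) -> int:
        row = self.assignments.loc[self.assignments["genome_id"] == genome_id]
        if row.empty:
            raise KeyError(genome_id)
        return int(row.iloc[0][f"{level}_cluster"])

    def to_frame(self) -> pd.DataFrame:
        return self.assignments.copy()


def cluster_matrix(m: SimilarityMatrix, method: str = DEFAULT_METHOD) -> Dendrogram:
    """Cluster the distance matrix ``100 - sim`` and derive the leaf order."""
    if method not in AGGLOMERATION_METHODS:
        raise ValueError(
            f"unknown agglomeration method {method!r}; "
            f"choose from {sorted(AGGLOMERATION_METHODS)}"
        )
    dist = m.distance()
    dist = (dist + dist.T) / 2.0  # absorb float-level asymmetry
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method=AGGLOMERATION_METHODS[method])
    leaves = hierarchy.leaves_list(linkage)
    leaf_order = [m.ids[i] for i in leaves]
    return Dendrogram(linkage=linkage, ids=list(m.ids), leaf_order=leaf_order, method=method)


def assign_clusters(
    m: SimilarityMatrix,
    dendrogram: Dendrogram,
    species_thr: float = 95.0,
    genus_thr: float = 70.0,
) -> ClusterTable:
    """Cut the dendrogram at ``100 - threshold`` for species and genus levels.

    Labels are consecutive integers starting at 1 in leaf order.  With
    ``genus_thr <= species_thr`` and a monotone linkage, species clusters are
    nested within genus clusters.
    """
    if not (0.0 <= genus_thr <= species_thr <= 100.0):
        raise ValueError(
            "thresholds must satisfy 0 <= genus_thr <= species_thr <= 100, "
            f"got genus={genus_thr}, species={species_thr}"
        )
    if dendrogram.ids != m.ids:
        raise ValueError("dendrogram does not belong to this matrix")

    def cut(threshold: float) -> dict[str, int]:
        raw = hierarchy.fcluster(
            dendrogram.linkage, t=100.0 - threshold, criterion="distance"
        )
        by_id = dict(zip(dendrogram.ids, raw))
        relabel: dict[int, int] = {}
        for gid in dendrogram.leaf_order:
            relabel.setdefault(by_id[gid], len(relabel) + 1)
        return {gid: relabel[by_id[gid]] for gid in dendrogram.ids}

    species = cut(species_thr)
    genus = cut(genus_thr)
    assignments = pd.DataFrame(
        {
            "genome_id": dendrogram.leaf_order,
            "species_cluster": [species[g] for g in dendrogram.leaf_order],
            "genus_cluster": [genus[g] for g in dendrogram.leaf_order],
        }
    )
    return ClusterTable(
        assignments=assignments,
        species_threshold=species_thr,
        genus_threshold=genus_thr,
    )


def order_matrix(m: SimilarityMatrix, leaf_order: list[str]) -> SimilarityMatrix:
    """Permute rows and columns of the matrix into the given leaf order."""
    return m.reorder(leaf_order)
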