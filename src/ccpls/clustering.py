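"""HVG clustering on filtered coefficients and report tables.

Genes whose filtered coefficients are all zero are dropped; the remaining
genes are clustered by k-means on their coefficient vectors, with the
cluster count chosen by the silhouette method over k in [2, 15].  Each
cluster is then summarised by its contributor cell types (neighbor types
with a consistently-signed nonzero coefficient across nearly all genes of
the cluster), a heat-map table and a bipartite edge table whose weights are
the cluster-averaged filtered coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "HVGClustering",
    "ContributorMap",
    "cluster_hvgs",
    "assign_contributors",
    "build_report",
]


@dataclass
class HVGClustering:
    """Clustering of reported HVGs on their filtered coefficient vectors."""

    gene_ids: list[str]
    labels: np.ndarray  # cluster index per gene, 1-based, size-ordered
    k: int
    silhouette_by_k: dict[int, float]
    cluster_means: np.ndarray  # k x L
    neighbor_types: list[str]
    degenerate: bool = False


@dataclass
class ContributorMap:
    """Per-cluster contributor cell types with direction and support."""

    contributors: dict[int, list[tuple[str, str, float]]] = field(
        default_factory=dict
    )  # cluster -> [(neighbor type, "up"/"down", support fraction)]


def cluster_hvgs(
    W_filtered: np.ndarray,
    gene_ids: list[str],
    neighbor_types: list[str],
    *,
    kmin: int = 2,
    kmax: int = 15,
    n_restarts: int = 10,
    seed: int | None = None,
) -> HVGClustering | None:
    """Cluster genes with >= 1 nonzero filtered coefficient.

    k-means (seeded, ``n_restarts`` initialisations) is run on the gene
    coefficient vectors for every k in ``[kmin, min(kmax, n_genes - 1)]``;
    the k with the highest mean silhouette wins, ties going to the smallest
    k.  Labels are renumbered 1..k by descending cluster size.  Returns
    ``None`` when no gene has a nonzero coefficient, and a degenerate
    single-cluster result when fewer than 2 clusterable genes (or fewer
    than kmin distinct coefficient patterns) remain.
    """
    W_filtered = np.asarray(W_filtered, dtype=float)
    nonzero = (W_filtered != 0).any(axis=0)
    if not nonzero.any():
        return None
    genes = [g for g, nz in zip(gene_ids, nonzero) if nz]
    V = W_filtered[:, nonzero].T  # genes x L feature matrix

    def _single_cluster() -> HVGClustering:
        logger.warning("degenerate clustering: single cluster forced")
        return HVGClustering(
            gene_ids=genes,
            labels=np.ones(len(genes), dtype=int),
            k=1,
            silhouette_by_k={},
            cluster_means=V.mean(axis=0, keepdims=True),
            neighbor_types=list(neighbor_types),
            degenerate=True,
        )

    n_genes = V.shape[0]
    kmax_eff = min(kmax, n_genes - 1, np.unique(V, axis=0).shape[0])
    if n_genes < 2 or kmax_eff < kmin:
        return _single_cluster()

    rng = np.random.default_rng(seed)
    sil: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(kmin, kmax_eff + 1):
        km = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(V)
        labelings[k] = km.labels_
        sil[k] = float(silhouette_score(V, km.labels_, metric="euclidean"))
    best_k = max(sorted(sil), key=lambda k: (sil[k], -k))
    raw_labels = labelings[best_k]

    # renumber 1..k by descending cluster size (stable on ties)
    sizes = np.bincount(raw_labels, minlength=best_k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(best_k, dtype=int)
    remap[order] = np.arange(1, best_k + 1)
    labels = remap[raw_labels]
    cluster_means = np.vstack(
        [V[labels == q].mean(axis=0) for q in range(1, best_k + 1)]
    )
    return HVGClustering(
        gene_ids=genes,
        labels=labels,
        k=best_k,
        silhouette_by_k=sil,
        cluster_means=cluster_means,
        neighbor_types=list(neighbor_types),
    )


def assign_contributors(
    clustering: HVGClustering,
    W_filtered: np.ndarray,
    gene_ids: list[str],
    *,
    support_threshold: float = 0.9,
) -> ContributorMap:
    """Assign contributor cell types to each HVG cluster.

    Neighbor type ``f`` contributes to cluster ``q`` when at least
    ``support_threshold`` of the cluster's genes carry a nonzero filtered
    coefficient for ``f`` and every such nonzero coefficient has the same
    sign; the shared sign gives the direction.
    """
    W_filtered = np.asarray(W_filtered, dtype=float)
    col = {g: i for i, g in enumerate(gene_ids)}
    idx = np.array([col[g] for g in clustering.gene_ids])
    out = ContributorMap()
    for q in sorted(set(clustering.labels.tolist())):
        sub = W_filtered[:, idx[clustering.labels == q]]  # L x n_q
        entries = []
        for fi, f in enumerate(clustering.neighbor_types):
            row = sub[fi]
            nz = row != 0
            support = float(nz.mean())
            if support >= support_threshold and nz.any():
                signs = np.sign(row[nz])
                if np.all(signs == signs[0]):
                    entries.append((f, "up" if signs[0] > 0 else "down", support))
        out.contributors[q] = entries
    return out


def build_report(
    clustering: HVGClustering,
    W_filtered: np.ndarray,
    gene_ids: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heat-map table and bipartite edge table.

    The heat map holds the filtered coefficients with rows = neighbor types
    and columns = reported HVGs ordered by cluster; each edge row is
    ``(cluster, neighbor type, mean filtered coefficient over the cluster's
    genes)``, with zero-mean edges omitted.
    """
    W_filtered = np.asarray(W_filtered, dtype=float)
    col = {g: i for i, g in enumerate(gene_ids)}
    order = np.argsort(clustering.labels, kind="stable")
    ordered_genes = [clustering.gene_ids[i] for i in order]
    heat = pd.DataFrame(
        W_filtered[:, [col[g] for g in ordered_genes]],
        index=clustering.neighbor_types,
        columns=ordered_genes,
    )
    rows = []
    for q in sorted(set(clustering.labels.tolist())):
        genes_q = [col[g] for g, lab in zip(clustering.gene_ids, clustering.labels)
                   if lab == q]
        means = W_filtered[:, genes_q].mean(axis=1)
        for f, mean in zip(clustering.neighbor_types, means):
            if mean != 0.0:
                rows.append({"cluster": q, "neighbor_type": f,
                             "mean_coefficient": float(mean)})
    edges = pd.DataFrame(rows, columns=["cluster", "neighbor_type",
                                        "mean_coefficient"])
    return heat, edges
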