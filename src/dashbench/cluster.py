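"""Cell filtering, PCA embedding, SNN-graph clustering and paired
clustering evaluation against simulated truth.

The filter keeps barcodes with more than 200 detected genes and stem-marker
expression of at least 2.5 on the log10(UMI-per-10,000 + 1) scale; in a
paired experiment a cell failing in either arm is eliminated from both, so
the two clusterings see identical cell sets.

Embedding is PCA on log-normalized, per-gene standardized (clipped at
±10) expression.  Single-batch synthetic replicates need no batch
integration, so no correction step sits between scaling and PCA (a
``batch_key`` hook is reserved for real multi-batch data).  Clustering
builds a k-nearest-neighbour graph on the leading components, converts it
to a shared-nearest-neighbour graph with Jaccard edge weights (edges below
1/15 pruned), and optimizes modularity (RB configuration null) at a given
resolution with a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set, Tuple

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .containers import UMIMatrix
from .de import lognormalize

log = logging.getLogger("dashbench")

__all__ = ["ClusterResult", "filter_cells", "embed", "snn_cluster",
           "compare_clusterings"]

SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterResult:
    """Cluster labels plus the parameters that produced them."""

    barcodes: np.ndarray
    labels: np.ndarray
    n_use: int
    k: int
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.barcodes, name="cluster")


def _marker_log10_cp10k(matrix: UMIMatrix, marker: str) -> np.ndarray:
    totals = matrix.totals().astype(float)
    counts = matrix.feature_counts(marker).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cp10k = np.where(totals > 0, counts / totals * 1e4, 0.0)
    return np.log10(cp10k + 1.0)


def filter_cells(matrix: UMIMatrix, marker: str, min_genes: int = 200,
                 marker_min: float = 2.5,
                 paired: Optional[UMIMatrix] = None) -> Set[str]:
    """Barcodes passing the complexity and stem-marker criteria.

    Keeps barcodes with strictly more than ``min_genes`` detected genes
    AND marker expression >= ``marker_min`` on the log10-cp10k scale.
    With ``paired`` given, a barcode must pass in *both* matrices
    (union-of-failures elimination); barcodes absent from the paired
    matrix fail there.
    """
    matrix.feature_index(marker)  # raises KeyError if absent
    genes = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    ok = (genes > min_genes) & (_marker_log10_cp10k(matrix, marker) >= marker_min)
    passing = set(np.asarray(matrix.barcodes)[ok])
    if paired is not None:
        passing &= filter_cells(paired, marker, min_genes, marker_min)
    return passing


def embed(matrix: UMIMatrix, n_components: int = 50,
          clip: float = 10.0) -> np.ndarray:
    """PCA embedding of log-normalized, per-gene standardized expression.

    Genes are centred and scaled to unit variance (zero-variance genes
    stay zero), values clipped at ``±clip``.  Components are ordered by
    decreasing explained variance; each component's sign is fixed by
    making its largest-magnitude gene loading positive, so the embedding
    is fully deterministic.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    norm, kept = lognormalize(matrix)
    if not kept.all():
        raise ValueError("zero-total barcodes cannot be embedded; filter first")
    x = np.asarray(norm.todense())
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.clip((x - mu) / sd, -clip, clip)
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if n_components > max_comp:
        log.warning("embed: reducing n_components %d -> %d (only %d cells)",
                    n_components, max_comp, x.shape[0])
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(x)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(emb.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            emb[:, j] *= -1.0
    return emb


def _snn_graph(embedding: np.ndarray, k: int) -> sp.csr_matrix:
    """Shared-nearest-neighbour graph with Jaccard weights.

    Neighbourhoods are each point plus its k-1 nearest neighbours
    (Euclidean); edge weight = |shared| / |union|, edges below the 1/15
    pruning threshold removed.
    """
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    shared = (adj @ adj.T).tocoo()
    jacc = shared.data / (2.0 * k - shared.data)
    keep = (jacc >= SNN_PRUNE) & (shared.row != shared.col)
    return sp.csr_matrix((jacc[keep], (shared.row[keep], shared.col[keep])),
                         shape=(n, n))


def snn_cluster(embedding: np.ndarray, n_use: int = 20, k: int = 20,
                resolution: float = 0.5, seed: int = 0,
                barcodes: Optional[Sequence[str]] = None) -> ClusterResult:
    """Modularity clustering of the SNN graph on the first ``n_use``
    embedding components.

    Labels are renumbered by decreasing cluster size (ties broken by the
    lowest member node id) and are identical across runs for a fixed seed.
    """
    if n_use > embedding.shape[1]:
        raise ValueError(f"n_use = {n_use} exceeds embedding dimensionality "
                         f"{embedding.shape[1]}")
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the {n} cells")
    snn = _snn_graph(embedding[:, :n_use], k)
    coo = sp.triu(snn, k=1).tocoo()
    g = igraph.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                     edge_attrs={"weight": coo.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=-1)
    raw = np.asarray(part.membership)
    # renumber by size desc, tie -> lowest member node id
    order = sorted(np.unique(raw),
                   key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])))
    remap = {c: i for i, c in enumerate(order)}
    labels = np.asarray([remap[c] for c in raw])
    if barcodes is None:
        barcodes = np.asarray([f"cell{i}" for i in range(n)], dtype=object)
    log.info("snn_cluster: %d cells -> %d clusters (res %.2f, k %d)",
             n, len(order), resolution, k)
    return ClusterResult(np.asarray(barcodes, dtype=object), labels,
                         n_use, k, resolution)


def _type_recovery(labels: np.ndarray, truth: np.ndarray) -> Dict:
    """For each truth type: its best-overlap cluster and whether that
    cluster's plurality truth type is the type itself."""
    out = {}
    for t in np.unique(truth):
        in_t = truth == t
        clusters, counts = np.unique(labels[in_t], return_counts=True)
        best = clusters[np.argmax(counts)]
        members = truth[labels == best]
        plurality = pd.Series(members).mode().iloc[0]
        out[t] = {"best_cluster": int(best), "recovered": bool(plurality == t)}
    return out


def compare_clusterings(result_u: ClusterResult, result_d: ClusterResult,
                        truth_labels: pd.Series) -> Dict:
    """Paired evaluation of the two arms' clusterings against truth.

    Computed over the barcodes labelled in both arms: cluster counts,
    adjusted Rand index of each arm vs truth and vs each other, and
    per-truth-type recovery (does the type map to a cluster it dominates).
    """
    su, sd = result_u.as_series(), result_d.as_series()
    shared = su.index.intersection(sd.index).intersection(truth_labels.index)
    lu = su.loc[shared].to_numpy()
    ld = sd.loc[shared].to_numpy()
    tr = truth_labels.loc[shared].to_numpy()
    report = {
        "n_cells": int(len(shared)),
        "n_clusters_untreated": result_u.n_clusters,
        "n_clusters_dashed": result_d.n_clusters,
        "ari_untreated_vs_truth": float(adjusted_rand_score(tr, lu)),
        "ari_dashed_vs_truth": float(adjusted_rand_score(tr, ld)),
        "ari_untreated_vs_dashed": float(adjusted_rand_score(lu, ld)),
        "recovery_untreated": _type_recovery(lu, tr),
        "recovery_dashed": _type_recovery(ld, tr),
    }
    report["n_types_recovered_untreated"] = sum(
        v["recovered"] for v in report["recovery_untreated"].values())
    report["n_types_recovered_dashed"] = sum(
        v["recovered"] for v in report["recovery_dashed"].values())
    return report
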