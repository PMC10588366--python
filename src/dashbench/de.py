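"""Normalization and Wilcoxon rank-sum differential expression.

Normalization is counts-per-10k with a log1p transform; the log base is a
parameter because two conventions coexist downstream: natural log for DE
(the dominant single-cell convention) and log10 for the stem-marker filter
threshold, which is quoted on the log10(UMI-per-10,000 + 1) scale.

The rank-sum test is exact (full enumeration over rank assignments, with
midranks for ties) when the pooled sample is small, and otherwise uses the
normal approximation with tie-corrected variance and continuity
correction.  Multiple testing is Bonferroni over the features that pass a
minimal prevalence prefilter (present in at least 3 cells overall).
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import UMIMatrix

log = logging.getLogger("dashbench")

__all__ = ["lognormalize", "wilcoxon_rank_sum", "pseudobulk_de",
           "count_expressed", "find_markers", "EXACT_MAX_N"]

#: largest pooled sample size for which the exact rank-sum null is enumerated
EXACT_MAX_N = 12

#: features must appear in at least this many cells to enter testing
MIN_CELLS_PREFILTER = 3


def lognormalize(matrix: UMIMatrix, scale: float = 1e4,
                 base: Optional[float] = None) -> Tuple[sp.csr_matrix, np.ndarray]:
    """log(count / barcode_total * scale + 1) per entry.

    ``base=None`` means natural log; pass ``base=10`` for the marker-filter
    scale.  Zero-total barcodes cannot be normalized: they are excluded,
    and the returned boolean mask marks the kept rows.

    Returns ``(normalized_csr, kept_row_mask)``.
    """
    totals = matrix.totals().astype(float)
    kept = totals > 0
    if not kept.all():
        log.warning("lognormalize: excluding %d zero-total barcodes",
                    int((~kept).sum()))
    x = sp.csr_matrix(matrix.counts[kept], dtype=float, copy=True)
    row_scale = scale / totals[kept]
    x.data *= np.repeat(row_scale, np.diff(x.indptr))
    np.log1p(x.data, out=x.data)
    if base is not None:
        x.data /= np.log(base)
    return x, kept


# ---------------------------------------------------------------------------
# rank-sum test


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_p(ranks: np.ndarray, nx: int, w: float) -> float:
    """Two-sided exact p: Pr(|W - E[W]| >= |w - E[W]|) by enumeration of
    all size-nx rank subsets."""
    n = len(ranks)
    mean = nx * (n + 1) / 2.0
    dev = abs(w - mean) - 1e-9
    hits = 0
    for idx in combinations(range(n), nx):
        if abs(ranks[list(idx)].sum() - mean) >= dev:
            hits += 1
    return hits / comb(n, nx)


def _normal_p(ranks: np.ndarray, nx: int, w: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(ranks)
    ny = n - nx
    mean = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / ((n) * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value for independent samples.

    Exact enumeration (midranks) when ``len(x)+len(y) <= EXACT_MAX_N``,
    else normal approximation with tie correction and continuity
    correction.  Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = _midranks(pooled)
    w = ranks[: x.size].sum()
    if pooled.size <= EXACT_MAX_N:
        return _exact_p(ranks, x.size, w)
    return _normal_p(ranks, x.size, w)


def _rank_sum_p_matrix(values: np.ndarray, group1: np.ndarray) -> np.ndarray:
    """Row-wise rank-sum p-values of a dense feature × cell matrix,
    comparing columns in ``group1`` against the rest (normal path only;
    used for the feature loops where pooled n is always large)."""
    n = values.shape[1]
    nx = int(group1.sum())
    ps = np.empty(values.shape[0])
    for i, row in enumerate(values):
        ranks = stats.rankdata(row, method="average")
        ps[i] = _normal_p(ranks, nx, ranks[group1].sum()) \
            if not np.all(row == row[0]) else 1.0
    return ps


def _mean_cp10k(matrix: UMIMatrix, rows: np.ndarray) -> np.ndarray:
    """Per-feature mean counts-per-10k over the given barcode rows."""
    sub = matrix.counts[rows]
    totals = np.asarray(sub.sum(axis=1)).ravel().astype(float)
    totals[totals == 0] = np.inf  # zero-total cells contribute 0 everywhere
    scaled = sp.diags(1e4 / totals) @ sub
    return np.asarray(scaled.mean(axis=0)).ravel()


def pseudobulk_de(matrix_u: UMIMatrix, matrix_d: UMIMatrix,
                  barcodes: Sequence[str], alpha: float = 0.05,
                  lfc_cutoff: float = 1.0) -> pd.DataFrame:
    """Pseudobulk DE of the depleted arm against the untreated arm.

    All ``barcodes`` (the shared cells) from both arms are pooled into one
    cell collection with a two-level group label; per feature, a Wilcoxon
    rank-sum test is run on natural-log-normalized values and the average
    log2 fold change is ``log2((mean cp10k_D + 1) / (mean cp10k_U + 1))``.
    Bonferroni m = number of features passing the prevalence prefilter.

    Returns one row per feature: avg_log2fc, pvalue, padj, pct_untreated,
    pct_dashed, significant_up/down flags at (alpha, lfc_cutoff).
    """
    common = matrix_u.features["id"].to_numpy()
    if not np.array_equal(common, matrix_d.features["id"].to_numpy()):
        ids = sorted(set(matrix_u.features["id"]) | set(matrix_d.features["id"]))
        raise ValueError("feature universes differ; align matrices first "
                         f"({len(ids)} distinct ids)")
    mu = matrix_u.subset_barcodes(barcodes)
    md = matrix_d.subset_barcodes(barcodes)

    norm_u, kept_u = lognormalize(mu)
    norm_d, kept_d = lognormalize(md)
    n_u, n_d = norm_u.shape[0], norm_d.shape[0]
    values = sp.vstack([norm_u, norm_d]).tocsc()
    group_d = np.zeros(n_u + n_d, dtype=bool)
    group_d[n_u:] = True

    n_cells_per_feature = np.asarray((values > 0).sum(axis=0)).ravel()
    tested = n_cells_per_feature >= MIN_CELLS_PREFILTER
    m = int(tested.sum())
    log.info("pseudobulk_de: testing %d/%d features (prefilter >= %d cells)",
             m, len(common), MIN_CELLS_PREFILTER)

    mean_u = _mean_cp10k(mu, np.flatnonzero(kept_u))
    mean_d = _mean_cp10k(md, np.flatnonzero(kept_d))
    log2fc = np.log2((mean_d + 1.0) / (mean_u + 1.0))
    pct_u = np.asarray((mu.counts > 0).sum(axis=0)).ravel() / max(mu.n_barcodes, 1)
    pct_d = np.asarray((md.counts > 0).sum(axis=0)).ravel() / max(md.n_barcodes, 1)

    pvals = np.ones(len(common))
    dense = np.asarray(values[:, tested].todense()).T  # tested features × cells
    pvals[tested] = _rank_sum_p_matrix(dense, group_d)
    padj = np.minimum(1.0, pvals * m)
    padj[~tested] = np.nan

    out = pd.DataFrame({
        "feature": common,
        "avg_log2fc": log2fc,
        "pvalue": pvals,
        "padj": padj,
        "pct_untreated": pct_u,
        "pct_dashed": pct_d,
        "tested": tested,
    })
    out["significant_down"] = (out["padj"] < alpha) & (out["avg_log2fc"] < -lfc_cutoff)
    out["significant_up"] = (out["padj"] < alpha) & (out["avg_log2fc"] > lfc_cutoff)
    return out


def count_expressed(matrix: UMIMatrix, labels: Sequence, cluster,
                    min_fraction: float = 0.25) -> int:
    """Number of features with >= 1 UMI in at least ``min_fraction`` of the
    cluster's cells (boundary inclusive)."""
    labels = np.asarray(labels)
    if len(labels) != matrix.n_barcodes:
        raise ValueError("labels must cover the matrix barcodes")
    rows = np.flatnonzero(labels == cluster)
    if rows.size == 0:
        return 0
    frac = np.asarray((matrix.counts[rows] > 0).sum(axis=0)).ravel() / rows.size
    return int((frac >= min_fraction).sum())


def find_markers(matrix: UMIMatrix, labels: Sequence, cluster,
                 alpha: float = 0.05, min_fraction: float = 0.25,
                 lfc_cutoff: float = 0.25) -> pd.DataFrame:
    """Marker genes of one cluster against all other cells.

    A feature is a marker when (1) Bonferroni-adjusted rank-sum p < alpha,
    (2) it is expressed in at least ``min_fraction`` of the cluster's
    cells, and (3) log2 fold change (cluster vs rest, +1-regularized mean
    cp10k) exceeds ``lfc_cutoff``.  A single-cluster labelling has no rest
    group: the result is empty and flagged (``attrs['error']``); a
    singleton cluster is flagged low-power but still tested.
    """
    labels = np.asarray(labels)
    if len(labels) != matrix.n_barcodes:
        raise ValueError("labels must cover the matrix barcodes")
    in_c = labels == cluster
    out_c = ~in_c
    empty = pd.DataFrame(columns=["feature", "avg_log2fc", "pvalue", "padj",
                                  "pct_cluster", "pct_rest", "marker"])
    if in_c.sum() == 0 or out_c.sum() == 0:
        empty.attrs["error"] = "no rest group to compare against"
        return empty
    if in_c.sum() == 1:
        log.warning("find_markers: singleton cluster %r, low power", cluster)

    norm, kept = lognormalize(matrix)
    in_k = in_c[kept]
    n_cells = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    tested = n_cells >= MIN_CELLS_PREFILTER
    m = int(tested.sum())

    pvals = np.ones(matrix.n_features)
    dense = np.asarray(norm.tocsc()[:, tested].todense()).T
    pvals[tested] = _rank_sum_p_matrix(dense, in_k)
    padj = np.minimum(1.0, pvals * m)

    mean_in = _mean_cp10k(matrix, np.flatnonzero(in_c))
    mean_out = _mean_cp10k(matrix, np.flatnonzero(out_c))
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    pct_in = np.asarray((matrix.counts[in_c] > 0).sum(axis=0)).ravel() / in_c.sum()
    pct_out = np.asarray((matrix.counts[out_c] > 0).sum(axis=0)).ravel() / out_c.sum()

    out = pd.DataFrame({
        "feature": matrix.features["id"].to_numpy(),
        "avg_log2fc": log2fc,
        "pvalue": pvals,
        "padj": padj,
        "pct_cluster": pct_in,
        "pct_rest": pct_out,
    })
    out["marker"] = ((out["padj"] < alpha) & (out["pct_cluster"] >= min_fraction)
                     & (out["avg_log2fc"] > lfc_cutoff) & tested)
    if in_c.sum() == 1:
        out.attrs["warning"] = "singleton cluster"
    return out
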