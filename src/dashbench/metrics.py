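"""Library-complexity analytics: read downsampling, UMI collapse,
per-cell metrics, rarefaction curves, paired regression and binned fold
changes.

Downsampling operates on reads (multivariate hypergeometric over
molecules) and then re-deduplicates, mirroring how libraries are
normalized to a fixed read total before comparison; thinning UMIs directly
would miss the saturation behaviour that read-level subsampling exposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import MoleculeTable, UMIMatrix

log = logging.getLogger("dashbench")

__all__ = [
    "downsample_reads", "collapse_umis", "per_cell_metrics", "rarefaction",
    "paired_regression", "binned_fold_change", "estimate_depletion",
    "RarefactionCurve",
]


def downsample_reads(molecules: MoleculeTable, depth: int,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> MoleculeTable:
    """Draw exactly ``depth`` reads without replacement from the read pool.

    Per-molecule surviving read counts follow the multivariate
    hypergeometric distribution; molecules with zero surviving reads are
    dropped, identities are otherwise unchanged.
    """
    total = molecules.total_reads
    if not 0 <= depth <= total:
        raise ValueError(f"depth {depth} outside [0, {total}]")
    if depth == total:
        return MoleculeTable(molecules.df.copy())
    if rng is None:
        rng = np.random.default_rng(seed)
    colors = molecules.df["reads"].to_numpy(dtype=np.int64)
    new_reads = rng.multivariate_hypergeometric(colors, depth, method="marginals")
    return molecules.with_reads(new_reads)


def collapse_umis(molecules: MoleculeTable,
                  features: Optional[pd.DataFrame] = None) -> UMIMatrix:
    """Count distinct molecules per (barcode, feature); reads discarded.

    Barcode and feature universes are the categories of the molecule
    table's columns, so features with zero surviving molecules keep their
    column.  ``features`` optionally supplies id/name metadata.
    """
    df = molecules.df
    bc = df["barcode"].astype("category")
    ft = df["feature"].astype("category")
    barcodes = np.asarray(bc.cat.categories, dtype=object)
    feature_ids = np.asarray(ft.cat.categories, dtype=object)
    shape = (len(barcodes), len(feature_ids))
    counts = sp.coo_matrix(
        (np.ones(len(df), dtype=np.int64), (bc.cat.codes, ft.cat.codes)),
        shape=shape).tocsr()
    counts.sum_duplicates()
    if features is None:
        features = pd.DataFrame({"id": feature_ids, "name": feature_ids})
    else:
        features = features.set_index("id").loc[feature_ids].reset_index()
    return UMIMatrix(counts, barcodes, features)


def per_cell_metrics(matrix: UMIMatrix, contaminant: str,
                     barcodes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-barcode complexity summary for the requested barcodes.

    Columns: total_umis, contaminant_umis, noncontaminant_umis,
    genes_detected (features with >= 1 UMI, contaminant included),
    pct_contaminant (0 by convention for zero-total barcodes), and
    ``missing`` flagging requested barcodes absent from the matrix
    (reported with zeros).
    """
    totals = matrix.totals()
    contam = matrix.feature_counts(contaminant)
    genes = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    full = pd.DataFrame({
        "total_umis": totals,
        "contaminant_umis": contam,
        "noncontaminant_umis": totals - contam,
        "genes_detected": genes,
    }, index=pd.Index(matrix.barcodes, name="barcode"))
    if barcodes is None:
        out = full
        out["missing"] = False
    else:
        req = pd.Index(barcodes)
        out = full.reindex(req)
        out["missing"] = out["total_umis"].isna()
        if out["missing"].any():
            log.warning("per_cell_metrics: %d requested barcodes absent, "
                        "reported as zeros", int(out["missing"].sum()))
        out = out.fillna(0)
        for c in ("total_umis", "contaminant_umis", "noncontaminant_umis",
                  "genes_detected"):
            out[c] = out[c].astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * out["contaminant_umis"] / out["total_umis"]
    out["pct_contaminant"] = pct.fillna(0.0)
    return out


@dataclass
class RarefactionCurve:
    """Median complexity per cell as a function of sequencing depth."""

    points: pd.DataFrame  # depth, median_genes, median_noncontaminant_umis

    def medians(self, column: str) -> np.ndarray:
        return self.points[column].to_numpy()


def rarefaction(molecules_u: MoleculeTable, molecules_d: MoleculeTable,
                depths: Sequence[int], barcodes: Sequence[str],
                contaminant: str, seed: int = 0
                ) -> Tuple[RarefactionCurve, RarefactionCurve]:
    """Rarefaction curves of both arms over shared barcodes.

    For each depth and arm: downsample reads, collapse UMIs, compute
    per-cell metrics over ``barcodes``, record the medians.
    """
    depths = sorted(int(d) for d in depths)
    curves = []
    ss = np.random.SeedSequence([seed, 7]).spawn(2 * len(depths))
    for arm_i, mols in enumerate((molecules_u, molecules_d)):
        rows = []
        for di, depth in enumerate(depths):
            rng = np.random.default_rng(ss[arm_i * len(depths) + di])
            sub = downsample_reads(mols, depth, rng=rng)
            m = per_cell_metrics(collapse_umis(sub), contaminant, barcodes)
            rows.append({
                "depth": depth,
                "median_genes": float(m["genes_detected"].median()),
                "median_noncontaminant_umis":
                    float(m["noncontaminant_umis"].median()),
            })
        curves.append(RarefactionCurve(pd.DataFrame(rows)))
    return curves[0], curves[1]


def paired_regression(metrics_u: pd.DataFrame, metrics_d: pd.DataFrame,
                      field: str = "genes_detected"
                      ) -> Tuple[float, float, float]:
    """OLS of the DASHed per-cell value on the untreated value (intercept
    included); returns ``(slope, intercept, r_squared)``.

    Slope > 1 with high R² indicates a uniform, cell-rank-preserving gain
    in complexity.
    """
    x = metrics_u[field].to_numpy(dtype=float)
    y = metrics_d.reindex(metrics_u.index)[field].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("paired regression needs at least 3 shared barcodes")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def binned_fold_change(metrics_u: pd.DataFrame, metrics_d: pd.DataFrame,
                       field: str = "genes_detected",
                       bin_edges: Optional[Sequence[float]] = None,
                       n_bins: int = 5) -> pd.DataFrame:
    """Distribution of the per-cell DASHed/untreated ratio across bins of
    the untreated value.

    Default bins are quantiles (quintiles) of the untreated distribution.
    Cells with untreated value 0 are excluded from ratios and counted in
    the ``n_zero_untreated`` attribute of the result.
    """
    x = metrics_u[field].to_numpy(dtype=float)
    y = metrics_d.reindex(metrics_u.index)[field].to_numpy(dtype=float)
    nz = x > 0
    ratios = y[nz] / x[nz]
    xnz = x[nz]
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(xnz, qs))
    bin_edges = np.asarray(bin_edges, dtype=float)
    if xnz.size and (xnz.min() < bin_edges[0] or xnz.max() > bin_edges[-1]):
        raise ValueError("bins do not cover the observed untreated range")
    idx = np.clip(np.searchsorted(bin_edges, xnz, side="right") - 1,
                  0, len(bin_edges) - 2)
    rows = []
    for b in range(len(bin_edges) - 1):
        r = ratios[idx == b]
        rows.append({
            "bin_low": bin_edges[b], "bin_high": bin_edges[b + 1],
            "n_cells": int(r.size),
            "median_ratio": float(np.median(r)) if r.size else np.nan,
            "q1_ratio": float(np.quantile(r, 0.25)) if r.size else np.nan,
            "q3_ratio": float(np.quantile(r, 0.75)) if r.size else np.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_zero_untreated"] = int((~nz).sum())
    return out


def estimate_depletion(matrix_u: UMIMatrix, matrix_d: UMIMatrix,
                       contaminant: str,
                       barcodes: Optional[Sequence[str]] = None) -> float:
    """Estimate the per-molecule cut probability from a paired experiment.

    Aggregating UMIs over ``barcodes`` (all shared barcodes by default),
    the contaminant odds against all other features drop from
    ``p/(1-p)`` to ``p(1-eps)/(1-p)`` under Bernoulli removal, so
    ``eps_hat = 1 - odds_depleted / odds_untreated``.
    """
    if barcodes is None:
        barcodes = sorted(set(matrix_u.barcodes) & set(matrix_d.barcodes))
    mu = per_cell_metrics(matrix_u, contaminant, barcodes)
    md = per_cell_metrics(matrix_d, contaminant, barcodes)
    odds_u = mu["contaminant_umis"].sum() / mu["noncontaminant_umis"].sum()
    odds_d = md["contaminant_umis"].sum() / md["noncontaminant_umis"].sum()
    return float(1.0 - odds_d / odds_u)
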