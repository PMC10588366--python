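"""Barcode-rank cell calling and the paired-arm barcode partition.

Cell callers assume cells carry far more UMIs than empty droplets.  When a
single ambient contaminant inflates empty-droplet totals, that assumption
breaks and ambient barcodes cross the rank threshold — the aberrant-calling
phenomenon this module quantifies by partitioning barcodes called in the
untreated and depleted arms and profiling the contaminant content of each
category.

The caller is the ordmag heuristic: threshold at one tenth of the 99th
percentile of the top ``expected_cells`` barcode totals.  It is scale- and
permutation-invariant and fully specified, which is what the benchmark
needs from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .containers import UMIMatrix
from .metrics import per_cell_metrics

log = logging.getLogger("dashbench")

__all__ = ["CellCallResult", "BarcodePartition", "call_cells",
           "partition_barcodes", "category_contaminant_stats"]


@dataclass
class CellCallResult:
    """Outcome of one cell-calling run."""

    called: Set[str]
    threshold: float
    expected_cells: int
    rank_curve: pd.DataFrame  # barcode, total_umis, rank (1 = largest)

    @property
    def n_called(self) -> int:
        return len(self.called)


@dataclass
class BarcodePartition:
    """Disjoint split of the union of two call sets."""

    untreated_only: Set[str]
    shared: Set[str]
    dashed_only: Set[str]


def call_cells(matrix: UMIMatrix, expected_cells: int) -> CellCallResult:
    """Ordmag cell calling on total UMIs per barcode.

    Sort totals descending; the threshold is the 99th percentile (linear
    interpolation) of the top ``expected_cells`` totals divided by 10;
    every barcode at or above the threshold is called.
    """
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    if matrix.n_barcodes == 0:
        raise ValueError("empty matrix")
    if expected_cells > matrix.n_barcodes:
        raise ValueError(
            f"expected_cells = {expected_cells} exceeds the "
            f"{matrix.n_barcodes} barcodes present")
    totals = matrix.totals()
    order = np.argsort(-totals, kind="stable")
    top = totals[order][:expected_cells]
    threshold = float(np.percentile(top, 99)) / 10.0
    called = set(np.asarray(matrix.barcodes)[totals >= threshold])
    curve = pd.DataFrame({
        "barcode": np.asarray(matrix.barcodes)[order],
        "total_umis": totals[order],
        "rank": np.arange(1, len(totals) + 1),
    })
    log.info("call_cells: threshold %.2f, %d/%d barcodes called",
             threshold, len(called), matrix.n_barcodes)
    return CellCallResult(called, threshold, expected_cells, curve)


def partition_barcodes(calls_u: CellCallResult,
                       calls_d: CellCallResult) -> BarcodePartition:
    """Untreated-only / shared / DASHed-only split of the two call sets."""
    u, d = calls_u.called, calls_d.called
    return BarcodePartition(untreated_only=u - d, shared=u & d,
                            dashed_only=d - u)


def _summary(pcts: np.ndarray) -> Dict[str, float]:
    return {
        "n": int(pcts.size),
        "median_pct": float(np.median(pcts)),
        "q1_pct": float(np.quantile(pcts, 0.25)),
        "q3_pct": float(np.quantile(pcts, 0.75)),
    }


def category_contaminant_stats(matrix_u: UMIMatrix, matrix_d: UMIMatrix,
                               partition: BarcodePartition,
                               contaminant: str) -> pd.DataFrame:
    """Contaminant content of each partition category.

    Untreated-only barcodes are profiled in the untreated matrix,
    DASHed-only in the depleted matrix, shared in both.  Zero-total
    barcodes are excluded from the summaries (with a warning); an empty
    category yields a row with ``n = 0`` and NaN quantiles.
    """
    spec = [
        ("untreated_only", sorted(partition.untreated_only), matrix_u, "untreated"),
        ("shared", sorted(partition.shared), matrix_u, "untreated"),
        ("shared", sorted(partition.shared), matrix_d, "dashed"),
        ("dashed_only", sorted(partition.dashed_only), matrix_d, "dashed"),
    ]
    rows = []
    for category, bcs, matrix, arm in spec:
        if not bcs:
            rows.append({"category": category, "arm": arm, "n": 0,
                         "median_pct": np.nan, "q1_pct": np.nan,
                         "q3_pct": np.nan})
            continue
        m = per_cell_metrics(matrix, contaminant, bcs)
        nonzero = m[m["total_umis"] > 0]
        if len(nonzero) < len(m):
            log.warning("category_contaminant_stats: %d zero-UMI barcodes "
                        "excluded from %s/%s", len(m) - len(nonzero),
                        category, arm)
        rows.append({"category": category, "arm": arm,
                     **_summary(nonzero["pct_contaminant"].to_numpy())})
    return pd.DataFrame(rows)
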