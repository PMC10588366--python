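"""In-memory containers shared across the pipeline.

`UMIMatrix` is a barcode × feature matrix of deduplicated molecule (UMI)
counts; on disk it lives as a Matrix Market triplet in the features ×
barcodes orientation, in memory it is presented barcode-major.

`MoleculeTable` is the read-level substrate: one row per captured cDNA
molecule, carrying its droplet barcode, feature, a molecule id unique
within the barcode, and the number of sequencing reads it received.
Depletion, amplification and read downsampling all operate on this table;
UMI collapsing reduces it to a `UMIMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised on malformed on-disk data or contract violations."""


@dataclass
class UMIMatrix:
    """Barcode-major sparse UMI count matrix with feature metadata.

    Attributes
    ----------
    counts
        CSR matrix of shape (n_barcodes, n_features), non-negative integers.
    barcodes
        Barcode strings, unique, in matrix row order.
    features
        DataFrame with columns ``id`` and ``name``, in matrix column order.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    features: pd.DataFrame

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.barcodes), len(self.features)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts must be non-negative")

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def feature_index(self, feature: str) -> int:
        """Column index of a feature id (or name as fallback)."""
        ids = self.features["id"].to_numpy()
        hits = np.flatnonzero(ids == feature)
        if hits.size == 0:
            hits = np.flatnonzero(self.features["name"].to_numpy() == feature)
        if hits.size == 0:
            raise KeyError(f"feature {feature!r} not in matrix")
        return int(hits[0])

    def totals(self) -> np.ndarray:
        """Total UMIs per barcode."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def feature_counts(self, feature: str) -> np.ndarray:
        """Per-barcode counts of one feature (dense vector)."""
        j = self.feature_index(feature)
        return np.asarray(self.counts[:, j].todense()).ravel()

    def subset_barcodes(self, barcodes: Sequence[str]) -> "UMIMatrix":
        """Rows for the given barcodes, in the given order (must exist)."""
        pos = pd.Index(self.barcodes).get_indexer(list(barcodes))
        if (pos < 0).any():
            missing = [b for b, p in zip(barcodes, pos) if p < 0]
            raise KeyError(f"barcodes not in matrix: {missing[:5]}...")
        return UMIMatrix(self.counts[pos], np.asarray(list(barcodes), dtype=object),
                         self.features.reset_index(drop=True))

    def drop_feature(self, feature: str) -> "UMIMatrix":
        """Matrix without one feature column (in-silico removal)."""
        j = self.feature_index(feature)
        keep = np.ones(self.n_features, dtype=bool)
        keep[j] = False
        return UMIMatrix(self.counts[:, keep], self.barcodes,
                         self.features.loc[keep].reset_index(drop=True))


MOLECULE_COLUMNS = ["barcode", "feature", "molecule", "reads"]
PROVENANCE_COLUMNS = ["is_cell", "cell_type"]


@dataclass
class MoleculeTable:
    """Read-level record of every captured cDNA molecule.

    ``df`` has columns barcode, feature (categoricals), molecule (int,
    unique within barcode), reads (int >= 1), and provenance flags
    ``is_cell`` (bool) and ``cell_type`` (int, -1 for ambient molecules).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in MOLECULE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"molecule table missing columns: {missing}")
        for c in PROVENANCE_COLUMNS:
            if c not in self.df.columns:
                self.df[c] = False if c == "is_cell" else -1

    def validate(self) -> "MoleculeTable":
        if len(self.df) and int(self.df["reads"].min()) < 1:
            raise FormatError("every retained molecule must have reads >= 1")
        dup = self.df.duplicated(subset=["barcode", "molecule"])
        if dup.any():
            raise FormatError("(barcode, molecule) pairs must be unique")
        return self

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_reads(self) -> int:
        return int(self.df["reads"].sum())

    def is_contaminant(self, contaminant: str) -> np.ndarray:
        return (self.df["feature"].to_numpy() == contaminant)

    def with_reads(self, reads: np.ndarray) -> "MoleculeTable":
        """Copy with a new read vector; molecules at 0 reads are dropped."""
        reads = np.asarray(reads)
        if len(reads) != len(self.df):
            raise ValueError("read vector length mismatch")
        out = self.df.copy()
        out["reads"] = reads
        out = out[out["reads"] > 0].reset_index(drop=True)
        return MoleculeTable(out)
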