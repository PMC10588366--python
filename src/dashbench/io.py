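"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices use the sparse-triplet convention of droplet scRNA-seq
tooling: ``matrix.mtx`` (Matrix Market, features × barcodes),
``barcodes.tsv`` (one barcode per line) and ``features.tsv`` (feature id,
feature name).  Gzipped companions are accepted transparently on read;
plain text is written.  Molecule tables and reports are TSV.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO

from .containers import FormatError, MoleculeTable, UMIMatrix

log = logging.getLogger("dashbench")

IUPAC_NT = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class MatrixTriplet:
    """Paths of one on-disk count-matrix triplet."""

    matrix_path: Path
    barcodes_path: Path
    features_path: Path

    @classmethod
    def in_dir(cls, directory: Union[str, Path]) -> "MatrixTriplet":
        d = Path(directory)
        return cls(d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv")


def _maybe_gz(path: Path) -> Path:
    if path.exists():
        return path
    gz = path.with_name(path.name + ".gz")
    if gz.exists():
        return gz
    raise FileNotFoundError(path)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_count_matrix(triplet: MatrixTriplet) -> UMIMatrix:
    """Read a triplet into a barcode-major :class:`UMIMatrix`.

    The matrix file stores features × barcodes; the result is transposed to
    barcodes × features.  Dimension mismatches with the companion files and
    non-integer entries raise :class:`FormatError` naming the offending
    file.
    """
    mpath = _maybe_gz(Path(triplet.matrix_path))
    bpath = _maybe_gz(Path(triplet.barcodes_path))
    fpath = _maybe_gz(Path(triplet.features_path))

    with _open_text(mpath) as fh:
        mat = scipy.io.mmread(fh)
    with _open_text(bpath) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_text(fpath) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    features = pd.DataFrame(
        {"id": [r[0] for r in rows],
         "name": [r[1] if len(r) > 1 else r[0] for r in rows]}
    )

    if mat.shape[0] != len(features):
        raise FormatError(
            f"{mpath} declares {mat.shape[0]} features but {fpath} has "
            f"{len(features)} lines"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{mpath} declares {mat.shape[1]} barcodes but {bpath} has "
            f"{len(barcodes)} lines"
        )
    data = np.asarray(sp.coo_matrix(mat).data)
    if data.size and not np.allclose(data, np.round(data)):
        raise FormatError(f"{mpath} contains non-integer entries")
    counts = sp.csr_matrix(mat.T).astype(np.int64)
    m = UMIMatrix(counts, np.asarray(barcodes, dtype=object), features)
    log.info("read_count_matrix: %d barcodes x %d features from %s",
             m.n_barcodes, m.n_features, mpath.parent)
    return m


def write_count_matrix(matrix: UMIMatrix, directory: Union[str, Path]) -> MatrixTriplet:
    """Write a triplet (features × barcodes on disk); inverse of
    :func:`read_count_matrix` on counts and order."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    triplet = MatrixTriplet.in_dir(d)
    scipy.io.mmwrite(str(triplet.matrix_path),
                     sp.coo_matrix(matrix.counts.T), field="integer")
    # mmwrite appends .mtx only if missing; path already ends in .mtx
    with open(triplet.barcodes_path, "w") as fh:
        fh.writelines(b + "\n" for b in matrix.barcodes)
    with open(triplet.features_path, "w") as fh:
        for _, row in matrix.features.iterrows():
            fh.write(f"{row['id']}\t{row['name']}\n")
    log.info("write_count_matrix: %d barcodes x %d features to %s",
             matrix.n_barcodes, matrix.n_features, d)
    return triplet


def read_fasta(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(identifier, sequence), ...]``.

    Sequences are uppercased, U is converted to T and whitespace stripped.
    An empty file or a character outside the IUPAC nucleotide codes is a
    :class:`FormatError` (the latter reported with its position).
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        seq = "".join(seq.split())
        for i, ch in enumerate(seq):
            if ch not in IUPAC_NT:
                raise FormatError(
                    f"{path}: record {rec.id!r} has non-IUPAC character "
                    f"{ch!r} at position {i + 1}"
                )
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_molecules(table: MoleculeTable, path: Union[str, Path]) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_molecules(path: Union[str, Path]) -> MoleculeTable:
    df = pd.read_csv(path, sep="\t")
    df["barcode"] = df["barcode"].astype("category")
    df["feature"] = df["feature"].astype("category")
    return MoleculeTable(df).validate()


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
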