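"""Readers, writers and preprocessing for expression matrices.

Counts come in as MatrixMarket triplets (with barcode/feature TSVs, 10x
convention: genes in rows) or dense TSV/CSV; preprocessing is library-size
log-normalization followed by gene centering, plus a variance-based
selection of highly variable genes.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)


def _read_id_file(path: Path) -> np.ndarray:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.array(ids, dtype=object)


def read_counts(
    path,
    fmt: str | None = None,
    barcodes=None,
    features=None,
    spots_in_rows: bool | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a counts matrix; returns ``(counts, spot_ids, gene_ids)``.

    MTX files follow the 10x convention (genes in rows) unless
    ``spots_in_rows=True``; barcode/feature TSVs default to ``barcodes.tsv``
    and ``features.tsv`` next to the matrix.  Dense TSV/CSV files are
    assumed spots-in-rows with a header of gene ids and a first column of
    spot ids unless ``spots_in_rows=False``.
    """
    path = Path(path)
    if fmt is None:
        suffixes = "".join(path.suffixes).lower()
        if ".mtx" in suffixes:
            fmt = "mtx"
        elif ".csv" in suffixes:
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "mtx":
        mat = sp.coo_matrix(scipy.io.mmread(str(path)))
        if spots_in_rows is None:
            spots_in_rows = False
        if not spots_in_rows:
            mat = mat.T  # genes-in-rows on disk
            logger.info("MTX read as genes-in-rows (10x convention); transposed")
        counts = np.asarray(mat.todense())
        bpath = Path(barcodes) if barcodes else path.parent / "barcodes.tsv"
        fpath = Path(features) if features else path.parent / "features.tsv"
        spot_ids = _read_id_file(bpath)
        gene_ids = _read_id_file(fpath)
        if spot_ids.shape[0] != counts.shape[0]:
            raise ValueError(
                f"{bpath}: {spot_ids.shape[0]} barcodes but matrix has "
                f"{counts.shape[0]} spots"
            )
        if gene_ids.shape[0] != counts.shape[1]:
            raise ValueError(
                f"{fpath}: {gene_ids.shape[0]} features but matrix has "
                f"{counts.shape[1]} genes"
            )
        return counts, spot_ids, gene_ids
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if spots_in_rows is False:
            df = df.T
        return (
            df.to_numpy(dtype=float),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_counts_mtx(counts, spot_ids, gene_ids, out_dir) -> None:
    """Write counts as matrix.mtx (genes in rows) + barcodes/features TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), sp.coo_matrix(np.asarray(counts).T))
    (out_dir / "barcodes.tsv").write_text("\n".join(map(str, spot_ids)) + "\n")
    (out_dir / "features.tsv").write_text("\n".join(map(str, gene_ids)) + "\n")


def log_normalize(counts, spot_ids=None, gene_ids=None) -> ExpressionMatrix:
    """Library-size log-normalization: x_ij = log(1 + c_ij * s_med / s_i).

    s_i is the library size (total counts) of spot i and s_med the median
    library size.  Spots with zero counts are dropped with a warning.  The
    result is NOT gene-centered; apply :meth:`ExpressionMatrix.center`
    before model fitting.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = counts.shape[0]
    lib = counts.sum(axis=1)
    keep = lib > 0
    if not keep.all():
        logger.warning("dropping %d all-zero spots", int((~keep).sum()))
    counts = counts[keep]
    lib = lib[keep]
    s_med = np.median(lib)
    X = np.log1p(counts * (s_med / lib)[:, None])
    em = ExpressionMatrix(X, None if spot_ids is None else np.asarray(spot_ids, object)[keep], gene_ids)
    return em


def center_genes(em: ExpressionMatrix) -> ExpressionMatrix:
    """Shift every gene column to mean zero (required by the model layer)."""
    return em.center()


def select_variable_genes(X, n_top: int = 2000, gene_ids=None) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes.

    Genes are ranked by the variance of their log-normalized expression
    (raw counts are log-normalized first); ties are broken
    deterministically by gene id.
    """
    if isinstance(X, ExpressionMatrix):
        values, ids = X.values, X.gene_ids
    else:
        values = np.asarray(X, dtype=float)
        is_counts = np.all(values >= 0) and np.allclose(values, np.round(values))
        if is_counts:
            values = log_normalize(values).values
        ids = np.asarray(gene_ids, object) if gene_ids is not None else np.array(
            [f"gene_{j}" for j in range(values.shape[1])], dtype=object
        )
    p = values.shape[1]
    if n_top > p:
        raise ValueError(f"n_top={n_top} exceeds the number of genes {p}")
    var = values.var(axis=0)
    order = np.lexsort((ids.astype(str), -var))
    return np.sort(order[:n_top])
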