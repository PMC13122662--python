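"""File formats and basic containers.

Count matrices live on disk as Matrix Market coordinate files with companion
one-column TSVs for row and column labels (``genes.tsv`` / ``barcodes.tsv``
style, no header).  On disk the MTX indices are 1-based per the standard;
in memory everything is 0-based.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer counts."""

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        n_genes, n_cells = self.matrix.shape
        if n_genes != len(self.genes):
            raise ValueError(
                f"matrix has {n_genes} rows but {len(self.genes)} gene labels"
            )
        if n_cells != len(self.barcodes):
            raise ValueError(
                f"matrix has {n_cells} columns but {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        """Column subset by integer index array (order preserved)."""
        index = np.asarray(index)
        return CountMatrix(
            self.matrix[:, index],
            self.genes,
            [self.barcodes[i] for i in index],
        )


@dataclass
class TagCountMatrix:
    """Dense hashtag x cell matrix (integer counts, real after normalization)."""

    matrix: np.ndarray
    hashtags: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.hashtags = list(self.hashtags)
        self.barcodes = list(self.barcodes)
        if self.matrix.ndim != 2:
            raise ValueError("tag matrix must be 2-D")
        if self.matrix.shape[0] != len(self.hashtags):
            raise ValueError("hashtag label count does not match matrix rows")
        if self.matrix.shape[1] != len(self.barcodes):
            raise ValueError("barcode count does not match matrix columns")
        if self.matrix.size and self.matrix.min() < 0:
            raise ValueError("tag counts must be non-negative")

    @property
    def n_tags(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]


def _read_labels(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"{what} label file not found: {path}")
    labels = pd.read_csv(path, sep="\t", header=None)[0].astype(str).tolist()
    return labels


def write_mtx(counts: CountMatrix | TagCountMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rows.tsv`` / ``<prefix>.cols.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mat = counts.matrix
    if isinstance(counts, TagCountMatrix):
        mat = sp.coo_matrix(mat)
        rows = counts.hashtags
    else:
        rows = counts.genes
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(mat))
    pd.Series(rows).to_csv(str(prefix) + ".rows.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.barcodes).to_csv(
        str(prefix) + ".cols.tsv", sep="\t", index=False, header=False
    )


def read_mtx(prefix: str | Path, kind: str = "counts") -> CountMatrix | TagCountMatrix:
    """Read a matrix written by :func:`write_mtx`.

    Parameters
    ----------
    kind
        ``"counts"`` (sparse genes x cells) or ``"tags"`` (dense hashtags x cells).
    """
    prefix = Path(prefix)
    mtx_path = Path(str(prefix) + ".mtx")
    if not mtx_path.exists():
        raise FileNotFoundError(f"matrix file not found: {mtx_path}")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # malformed header / truncated entries
        raise ValueError(f"failed to parse Matrix Market file {mtx_path}: {exc}") from exc
    rows = _read_labels(Path(str(prefix) + ".rows.tsv"), "row")
    cols = _read_labels(Path(str(prefix) + ".cols.tsv"), "column")
    if mat.shape != (len(rows), len(cols)):
        raise ValueError(
            f"{mtx_path}: matrix is {mat.shape} but labels give "
            f"({len(rows)}, {len(cols)})"
        )
    if kind == "tags":
        return TagCountMatrix(np.asarray(sp.coo_matrix(mat).todense()), rows, cols)
    return CountMatrix(sp.csr_matrix(mat), rows, cols)


def qc_mapping_summary(mapped_reads: int, total_reads: int) -> float:
    """Percent of reads mapped, rounded half-up to one decimal.

    Matches the conventional read-accounting line of a sequencing methods
    section (e.g. 1,254,839,844 of 1,800,071,774 reads -> 69.7).
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mapped_reads < 0 or mapped_reads > total_reads:
        raise ValueError("mapped_reads must lie in [0, total_reads]")
    pct = decimal.Decimal(mapped_reads) * 100 / decimal.Decimal(total_reads)
    return float(pct.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))
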