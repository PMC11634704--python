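"""Sparse count-matrix I/O, QC filtering and log-normalization.

Matrices are held gene-major: a CSC matrix of shape ``(n_cells, n_genes)``
so that each compressed column is one gene's nonzero values across cells.
This is the orientation the rank engine consumes — a gene's nonzeros (and
their cell indices) are a contiguous slice of ``data``/``indices``.

On disk the CellRanger convention is used: Matrix Market coordinate files
with genes as rows and cells (barcodes) as columns, plus ``genes.tsv`` and
``barcodes.tsv`` with one identifier per line.  Cell annotations travel as a
TSV with header columns ``cell_id, donor_id, cell_type, age_years, sex``
(optionally ``pct_mito``); the barcode file is authoritative for cell order
and annotation rows are re-ordered to match it.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "SparseCounts",
    "QCThresholds",
    "read_mtx",
    "write_mtx",
    "read_cell_table",
    "read_gene_list",
    "attach_qc_stats",
    "percent_mito",
    "qc_filter",
    "log_normalize",
    "orient_gene_major",
]

ANNOT_COLUMNS = ("cell_id", "donor_id", "cell_type", "age_years", "sex")


class FormatError(ValueError):
    """Structural problem in an input file (shape/header mismatch)."""


class DataError(ValueError):
    """Well-formed file with invalid content (negative/non-integer counts...)."""


@dataclasses.dataclass
class SparseCounts:
    """Gene-major sparse expression matrix with cell/gene identifiers.

    ``matrix`` is CSC of shape ``(n_cells, n_genes)``; stored values are
    strictly positive (zeros are implicit).  ``layer`` is ``"raw"`` for
    integer UMI counts or ``"lognorm"`` for log-normalized values.
    """

    matrix: sp.csc_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.matrix = sp.csc_matrix(self.matrix)
        self.matrix.eliminate_zeros()
        self.validate()

    # -- axis metadata -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        if self.layer not in ("raw", "lognorm"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.matrix.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DataError("cell_ids are not unique")
        d = self.matrix.data
        if d.size:
            if not np.all(np.isfinite(d)):
                raise DataError("matrix contains NaN or Inf")
            if d.min() <= 0:
                raise DataError("stored values must be strictly positive")
            if self.layer == "raw" and np.any(d != np.floor(d)):
                raise DataError("raw layer requires integer counts")

    # -- derived per-cell stats ---------------------------------------
    def cell_totals(self) -> np.ndarray:
        """Total stored value per cell (UMI count for the raw layer)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of nonzero genes per cell."""
        return np.asarray((self.matrix != 0).sum(axis=1)).ravel()

    # -- subsetting ----------------------------------------------------
    def subset_cells(self, index: np.ndarray) -> "SparseCounts":
        """New SparseCounts restricted to the given cell positions (in order)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SparseCounts(
            sp.csc_matrix(self.matrix[index, :]),
            self.gene_ids,
            self.cell_ids[index],
            layer=self.layer,
        )

    def subset_genes(self, index: np.ndarray) -> "SparseCounts":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SparseCounts(
            sp.csc_matrix(self.matrix[:, index]),
            self.gene_ids[index],
            self.cell_ids,
            layer=self.layer,
        )


@dataclasses.dataclass
class QCThresholds:
    """Cell-level QC cutoffs.

    Cells are retained when ``min_genes <= genes detected <= max_genes``,
    total UMI is at most ``max_umi`` and mitochondrial percentage at most
    ``max_pct_mito``.  The gene floor removes empty droplets; the gene and
    UMI ceilings remove likely doublets; the mitochondrial ceiling removes
    damaged cells (per-dataset practice varies over roughly 5-20%, so the
    default sits at the permissive end and should be tuned per run).
    """

    min_genes: int = 500
    max_genes: int = 5000
    max_umi: int = 40000
    max_pct_mito: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValueError("need 0 < min_genes < max_genes")
        if self.max_umi <= 0 or self.max_pct_mito <= 0:
            raise ValueError("thresholds must be positive")


def _read_id_file(path: str | Path) -> np.ndarray:
    """One identifier per line; for multi-column 10x files, the first column."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return np.asarray(ids, dtype=object)


def read_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    layer: str = "raw",
) -> SparseCounts:
    """Read a CellRanger-style triplet (matrix.mtx, genes.tsv, barcodes.tsv).

    The .mtx stores genes as rows and cells as columns; the result is
    transposed to the package's gene-major (cells x genes) orientation.
    Duplicate (gene, cell) triplets are summed and explicit zeros dropped.
    """
    genes = _read_id_file(genes_path)
    cells = _read_id_file(barcodes_path)
    try:
        m = mmread(str(matrix_path))
    except ValueError as exc:
        raise FormatError(f"cannot parse {matrix_path}: {exc}") from exc
    if m.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix is {m.shape[0]} x {m.shape[1]} but gene/barcode files "
            f"list {len(genes)} genes and {len(cells)} cells"
        )
    if m.data.size and m.data.min() < 0:
        raise DataError("negative count in matrix")
    if layer == "raw" and m.data.size and np.any(m.data != np.floor(m.data)):
        raise DataError("non-integer count in raw matrix")
    # tocsc() sums duplicate coordinate entries (CellRanger convention)
    return SparseCounts(sp.csc_matrix(m.T), genes, cells, layer=layer)


def write_mtx(
    counts: SparseCounts,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write the CellRanger-style triplet; integer field for raw, real for lognorm."""
    m = counts.matrix.T.tocoo()
    if counts.layer == "raw":
        m = m.astype(np.int64)
        mmwrite(str(matrix_path), m, field="integer")
    else:
        mmwrite(str(matrix_path), m, field="real")
    for path, ids in ((genes_path, counts.gene_ids), (barcodes_path, counts.cell_ids)):
        with open(path, "w") as fh:
            fh.write("\n".join(str(i) for i in ids) + "\n")


def read_cell_table(path: str | Path, cell_ids: Sequence[str]) -> pd.DataFrame:
    """Read annotations and re-order rows to the barcode order.

    Every cell in ``cell_ids`` must be annotated; annotation rows for
    unknown cells are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "donor_id": str})
    missing_cols = [c for c in ANNOT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"annotation file lacks columns {missing_cols}")
    if df["cell_id"].duplicated().any():
        raise DataError("duplicate cell_id in annotation file")
    df = df.set_index("cell_id", drop=False)
    cell_ids = [str(c) for c in cell_ids]
    unknown = df.index.difference(cell_ids)
    if len(unknown):
        warnings.warn(f"dropping {len(unknown)} annotation rows not in the matrix")
    absent = [c for c in cell_ids if c not in df.index]
    if absent:
        raise DataError(f"{len(absent)} cells lack annotations (first: {absent[0]})")
    return df.loc[cell_ids].reset_index(drop=True)


def read_gene_list(path: str | Path) -> list[str]:
    """Gene symbols, one per line; blank lines ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def attach_qc_stats(counts: SparseCounts, cells: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite ``n_genes_detected`` and ``total_umi`` computed from the matrix."""
    if counts.layer != "raw":
        raise ValueError("QC stats are defined on the raw layer")
    out = cells.copy()
    out["n_genes_detected"] = counts.genes_detected()
    out["total_umi"] = counts.cell_totals().astype(np.int64)
    return out


def percent_mito(counts: SparseCounts, prefix: str = "MT-") -> np.ndarray:
    """Percent of each cell's UMIs on genes whose id starts with ``prefix``.

    Convenience for datasets that ship no pct_mito column; the analysis
    itself treats pct_mito as a provided annotation because published
    per-dataset cutoffs (and gene naming schemes) vary.
    """
    if counts.layer != "raw":
        raise ValueError("percent_mito is defined on the raw layer")
    is_mt = np.array([str(g).startswith(prefix) for g in counts.gene_ids])
    totals = counts.cell_totals()
    if not is_mt.any():
        return np.zeros(counts.n_cells)
    mito = np.asarray(counts.matrix[:, is_mt].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito / totals, 0.0)
    return pct


def qc_filter(
    cells: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Boolean keep-mask over cells plus per-criterion removal counts.

    A cell passes when ``min_genes <= n_genes_detected <= max_genes``,
    ``total_umi <= max_umi`` and ``pct_mito <= max_pct_mito``.  Removal
    counts are non-exclusive (a cell can fail several criteria).
    """
    t = thresholds or QCThresholds()
    if len(cells) == 0:
        return np.zeros(0, dtype=bool), {
            "low_genes": 0, "high_genes": 0, "high_umi": 0, "high_mito": 0
        }
    ng = cells["n_genes_detected"].to_numpy()
    umi = cells["total_umi"].to_numpy()
    mito = cells["pct_mito"].to_numpy() if "pct_mito" in cells else np.zeros(len(cells))
    fails = {
        "low_genes": ng < t.min_genes,
        "high_genes": ng > t.max_genes,
        "high_umi": umi > t.max_umi,
        "high_mito": mito > t.max_pct_mito,
    }
    mask = ~np.logical_or.reduce(list(fails.values()))
    return mask, {k: int(v.sum()) for k, v in fails.items()}


def log_normalize(counts: SparseCounts, scale_factor: float = 1e4) -> SparseCounts:
    """Depth-normalize and log-transform: v -> ln(1 + v * scale_factor / T).

    ``T`` is the cell's total UMI count.  The sparsity pattern is unchanged
    (log1p(0) = 0) and within-cell value order is preserved.  Cells with
    zero total UMI cannot be normalized and raise an error naming the first
    offender — run qc_filter first.
    """
    if counts.layer != "raw":
        raise ValueError("log_normalize expects the raw layer")
    totals = counts.cell_totals()
    if np.any(totals == 0):
        bad = counts.cell_ids[int(np.argmax(totals == 0))]
        raise DataError(f"cell {bad!r} has zero total UMI; filter it out first")
    m = counts.matrix.tocoo()
    data = np.log1p(m.data * (scale_factor / totals[m.row]))
    out = sp.csc_matrix((data, (m.row, m.col)), shape=m.shape)
    return SparseCounts(out, counts.gene_ids, counts.cell_ids, layer="lognorm")


def orient_gene_major(
    matrix: sp.spmatrix,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    genes_axis: int = 0,
    layer: str = "raw",
) -> SparseCounts:
    """Wrap an arbitrary sparse matrix as gene-major SparseCounts.

    ``genes_axis`` says which axis of ``matrix`` indexes genes; axis 0
    (genes x cells, the on-disk convention) is transposed.  The triplet
    multiset and all per-gene sums are preserved exactly.
    """
    if genes_axis == 0:
        matrix = matrix.T
    elif genes_axis != 1:
        raise ValueError("genes_axis must be 0 or 1")
    return SparseCounts(sp.csc_matrix(matrix), gene_ids, cell_ids, layer=layer)
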