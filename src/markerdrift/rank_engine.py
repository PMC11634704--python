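"""Single-pass sparse one-vs-all-others Wilcoxon rank-sum engine.

For each gene (one CSC column) the nonzero values are sorted once and
assigned midranks; the implicit zeros, being the smallest values, share the
single midrank ``(n_zero + 1) / 2``.  Per-class rank sums are then
accumulated in one sequential pass over the stored values (O(#classes)
memory), and every class's one-vs-rest Mann-Whitney U statistic, z score
and two-sided p-value fall out of the same sorted column — the column is
never re-sorted per class, which is what makes the all-classes-at-once
loop order cheap.

The normal approximation uses the tie-corrected variance

    sigma^2 = n1 * n2 / 12 * [(n + 1) - T / (n * (n - 1))],   T = sum(t^3 - t)

over tie groups (the zero block included), with an optional 0.5 continuity
correction applied toward the mean, and p = erfc(|z| / sqrt(2)) two-sided.
With continuity on (the default) this reproduces R's ``wilcox.test``
asymptotic p-values, the convention marker detection pipelines assume.
Since ranks are invariant under strictly increasing transforms, raw counts
and log-normalized values give identical p-values.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import erfc

from .sparse_io import SparseCounts

__all__ = [
    "RankedColumn",
    "ClassRankSums",
    "TestResultMatrix",
    "rank_column",
    "accumulate_rank_sums",
    "u_to_p",
    "wilcoxon_one_vs_rest",
]


@dataclasses.dataclass
class RankedColumn:
    """Midranks of one sparse gene column.

    ``nz_ranks[i]`` is the midrank of stored value i (aligned with the
    input order, not the sorted order); ``rows[i]`` is its cell index.
    All ``n_zero`` implicit zeros share ``zero_rank = (n_zero + 1) / 2``.
    ``tie_sizes`` lists every tie-group size (zero block first when
    present) and sums to ``n``.
    """

    n: int
    rows: np.ndarray
    nz_ranks: np.ndarray
    zero_rank: float
    tie_sizes: np.ndarray

    @property
    def n_zero(self) -> int:
        return self.n - len(self.nz_ranks)

    @property
    def tie_term(self) -> float:
        """T = sum over tie groups of t^3 - t (zero block included)."""
        t = self.tie_sizes.astype(np.float64)
        return float(np.sum(t**3 - t))


@dataclasses.dataclass
class ClassRankSums:
    """Per-class rank sums for one gene, plus the shared tie-correction term."""

    classes: np.ndarray
    rank_sums: np.ndarray
    class_sizes: np.ndarray
    tie_term: float
    n: int


@dataclasses.dataclass
class TestResultMatrix:
    """One-vs-rest test results: arrays of shape (n_classes, n_genes)."""

    classes: np.ndarray
    genes: np.ndarray
    u: np.ndarray
    z: np.ndarray
    p: np.ndarray
    rank_sums: np.ndarray
    class_sizes: np.ndarray  # (n_classes,)
    tie_terms: np.ndarray  # (n_genes,)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (class, gene, U, z, p) table, classes varying slowest."""
        n_c, n_g = self.p.shape
        return pd.DataFrame(
            {
                "class": np.repeat(self.classes, n_g),
                "gene": np.tile(self.genes, n_c),
                "U": self.u.ravel(),
                "z": self.z.ravel(),
                "p": self.p.ravel(),
            }
        )


def rank_column(
    values: np.ndarray, n: int, rows: np.ndarray | None = None
) -> RankedColumn:
    """Midrank a sparse column of ``n`` cells with stored values ``values``.

    Zeros (implicit) occupy ranks ``1..n_zero`` and collapse to the midrank
    ``(n_zero + 1) / 2``; sorted nonzeros continue from rank ``n_zero + 1``
    with ties averaged.  ``rows`` gives the cell index of each stored value
    (defaults to 0..len(values)-1 for dense-style input).
    """
    values = np.asarray(values, dtype=np.float64)
    if rows is None:
        rows = np.arange(len(values))
    rows = np.asarray(rows)
    if len(rows) != len(values):
        raise ValueError("rows and values length mismatch")
    if len(values) > n:
        raise ValueError("more stored values than cells")
    if values.size and values.min() <= 0:
        raise ValueError("stored values must be strictly positive")
    n_zero = n - len(values)
    zero_rank = (n_zero + 1) / 2.0
    if values.size == 0:
        return RankedColumn(n, rows, values, zero_rank, np.array([n_zero]))

    order = np.argsort(values, kind="stable")
    sv = values[order]
    # tie-group boundaries in the sorted nonzeros
    starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
    ends = np.r_[starts[1:], len(sv)]
    sizes = ends - starts
    # group occupying sorted slots [s, e) holds ranks n_zero+s+1 .. n_zero+e
    midranks_grp = n_zero + (starts + ends + 1) / 2.0
    ranks_sorted = np.repeat(midranks_grp, sizes)
    nz_ranks = np.empty_like(ranks_sorted)
    nz_ranks[order] = ranks_sorted
    tie_sizes = sizes if n_zero == 0 else np.r_[n_zero, sizes]
    return RankedColumn(n, rows, nz_ranks, zero_rank, tie_sizes)


def accumulate_rank_sums(
    ranked: RankedColumn, labels: Sequence, codes: np.ndarray | None = None,
    n_classes: int | None = None,
) -> ClassRankSums:
    """Sum ranks per class in one pass over the stored values.

    The implicit zeros of class c contribute ``(n_c - nnz_c) * zero_rank``
    in closed form, so each stored value is visited exactly once however
    many classes there are.  ``codes``/``n_classes`` let callers pass
    pre-factorized labels (first-appearance order) to avoid refactorizing
    per gene.
    """
    if codes is None:
        classes, codes = _factorize(labels)
        n_classes = len(classes)
    else:
        classes = np.asarray(labels, dtype=object)
        if n_classes is None:
            n_classes = len(classes)
    codes = np.asarray(codes)
    if len(codes) != ranked.n:
        raise ValueError("label vector length does not match cell count")
    n_c = np.bincount(codes, minlength=n_classes).astype(np.float64)
    nnz_c = np.bincount(codes[ranked.rows], minlength=n_classes).astype(np.float64)
    nz_sum = np.bincount(
        codes[ranked.rows], weights=ranked.nz_ranks, minlength=n_classes
    )
    rank_sums = nz_sum + (n_c - nnz_c) * ranked.zero_rank
    return ClassRankSums(classes, rank_sums, n_c, ranked.tie_term, ranked.n)


def u_to_p(
    rank_sums: np.ndarray,
    class_sizes: np.ndarray,
    n: int,
    tie_term: float | np.ndarray,
    continuity: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert rank sums to (U, z, two-sided p) under the normal approximation.

    U = R - n1(n1+1)/2; mean n1*n2/2; tie-corrected variance as in the
    module docstring.  With ``continuity`` a 0.5 correction is applied
    toward the mean before dividing by sigma.  Degenerate columns
    (sigma^2 = 0, every value tied) return z = 0, p = 1.
    """
    r = np.asarray(rank_sums, dtype=np.float64)
    n1 = np.asarray(class_sizes, dtype=np.float64)
    if np.any((n1 < 1) | (n1 > n - 1)):
        raise ValueError("each class must be a proper nonempty subset of cells")
    n2 = n - n1
    u = r - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - np.asarray(tie_term) / (n * (n - 1.0)))
    var = np.maximum(var, 0.0)  # guard tiny negative round-off
    z0 = u - mu
    if continuity:
        z0 = z0 - np.sign(z0) * 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, z0 / np.sqrt(var), 0.0)
    p = erfc(np.abs(z) / np.sqrt(2.0))
    p = np.where(var > 0, p, 1.0)
    return u, z, np.minimum(p, 1.0)


def _factorize(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Dense class codes 0..C-1 in first-appearance order."""
    codes, classes = pd.factorize(np.asarray(labels), sort=False)
    if (codes < 0).any():
        raise ValueError("labels contain missing values")
    return np.asarray(classes, dtype=object), codes


def wilcoxon_one_vs_rest(
    matrix: SparseCounts | sp.spmatrix,
    labels: Sequence,
    continuity: bool = True,
) -> TestResultMatrix:
    """One-vs-all-others Wilcoxon rank-sum test for every (class, gene).

    ``matrix`` is gene-major (cells x genes CSC; a SparseCounts or a bare
    scipy sparse matrix).  Iterates genes in the outer loop; each gene's
    column is sorted exactly once and the rank sums of all classes are
    accumulated simultaneously from it.  Returns a classes x genes result;
    row order is first appearance of each label.
    """
    if isinstance(matrix, SparseCounts):
        genes = matrix.gene_ids
        m = matrix.matrix
    else:
        m = sp.csc_matrix(matrix)
        genes = np.arange(m.shape[1])
    labels = np.asarray(labels)
    if len(labels) != m.shape[0]:
        raise ValueError("labels length does not match number of cells")
    classes, codes = _factorize(labels)
    n_classes = len(classes)
    if n_classes < 2:
        raise ValueError("need at least 2 classes for a one-vs-rest test")
    n = m.shape[0]
    n_genes = m.shape[1]
    class_sizes = np.bincount(codes, minlength=n_classes).astype(np.float64)

    rank_sums = np.empty((n_classes, n_genes))
    tie_terms = np.empty(n_genes)
    indptr, indices, data = m.indptr, m.indices, m.data
    for g in range(n_genes):
        lo, hi = indptr[g], indptr[g + 1]
        ranked = rank_column(data[lo:hi], n, rows=indices[lo:hi])
        acc = accumulate_rank_sums(ranked, classes, codes=codes, n_classes=n_classes)
        rank_sums[:, g] = acc.rank_sums
        tie_terms[g] = acc.tie_term

    u, z, p = u_to_p(
        rank_sums, class_sizes[:, None], n, tie_terms[None, :], continuity=continuity
    )
    return TestResultMatrix(
        classes=classes,
        genes=np.asarray(genes),
        u=u,
        z=z,
        p=p,
        rank_sums=rank_sums,
        class_sizes=class_sizes,
        tie_terms=tie_terms,
    )
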