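"""Marker-gene detection: fold changes, detection fractions, p adjustment.

Combines the rank engine with the standard cluster-marker criteria: a gene
is a marker for class c when its log fold change exceeds the threshold,
its adjusted p-value is below alpha, and it is detected in more than
``min_pct`` of cells in either the class or the rest.  Fold change follows
the de-logged-mean convention: with log-normalized values x,

    log_fc = log2( (mean_c exp(x)-1 + pc) / (mean_rest exp(x)-1 + pc) )

with pseudocount pc = 1 by default (natural-log base available).  The
default multiple-testing correction is Bonferroni over all genes, matching
the convention of the FindAllMarkers-style tools this module replaces;
Benjamini-Hochberg is available.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .rank_engine import _factorize, wilcoxon_one_vs_rest
from .sparse_io import SparseCounts

__all__ = [
    "MarkerParams",
    "fold_change",
    "adjust_p",
    "find_all_markers",
    "marker_counts",
]

MARKER_COLUMNS = ["class", "gene", "log_fc", "pct_1", "pct_2", "p", "p_adj", "is_marker"]


@dataclasses.dataclass
class MarkerParams:
    """Thresholds and conventions for marker calling."""

    logfc_threshold: float = 0.5
    alpha: float = 0.05
    min_pct: float = 0.1
    adjust_method: str = "bonferroni"
    fc_base: str = "log2"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.logfc_threshold < 0 or self.min_pct < 0 or self.pseudocount <= 0:
            raise ValueError("thresholds must be positive")
        if self.adjust_method not in ("bonferroni", "bh"):
            raise ValueError("adjust_method must be 'bonferroni' or 'bh'")
        if self.fc_base not in ("log2", "ln"):
            raise ValueError("fc_base must be 'log2' or 'ln'")


def _class_stats(
    m: sp.csc_matrix, codes: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(expm1 sums, nonzero counts) per class per gene, plus class sizes."""
    onehot = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_classes, len(codes)),
    )
    expm = m.copy()
    expm.data = np.expm1(expm.data)
    sums = np.asarray((onehot @ expm).todense())
    nnz = m.copy()
    nnz.data = np.ones_like(nnz.data)
    counts = np.asarray((onehot @ nnz).todense())
    sizes = np.bincount(codes, minlength=n_classes).astype(np.float64)
    return sums, counts, sizes


def _fold_change_all(
    m: sp.csc_matrix,
    codes: np.ndarray,
    n_classes: int,
    params: MarkerParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log_fc, pct_1, pct_2) arrays of shape (n_classes, n_genes)."""
    sums, counts, sizes = _class_stats(m, codes, n_classes)
    tot_sum = sums.sum(axis=0, keepdims=True)
    tot_cnt = counts.sum(axis=0, keepdims=True)
    n = sizes.sum()
    mean_in = sums / sizes[:, None]
    mean_out = (tot_sum - sums) / (n - sizes)[:, None]
    log = np.log2 if params.fc_base == "log2" else np.log
    log_fc = log(mean_in + params.pseudocount) - log(mean_out + params.pseudocount)
    pct_1 = counts / sizes[:, None]
    pct_2 = (tot_cnt - counts) / (n - sizes)[:, None]
    return log_fc, pct_1, pct_2


def fold_change(
    matrix: SparseCounts,
    labels: Sequence,
    class_label,
    params: MarkerParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (log_fc, pct_1, pct_2) for one class versus all others."""
    params = params or MarkerParams()
    if matrix.layer != "lognorm":
        raise ValueError("fold_change expects the lognorm layer")
    classes, codes = _factorize(labels)
    hits = np.flatnonzero(classes == class_label)
    if len(hits) == 0:
        raise ValueError(f"class {class_label!r} not present")
    c = int(hits[0])
    sizes = np.bincount(codes, minlength=len(classes))
    if sizes[c] == len(codes):
        raise ValueError("class covers every cell; complement is empty")
    log_fc, pct_1, pct_2 = _fold_change_all(matrix.matrix, codes, len(classes), params)
    return log_fc[c], pct_1[c], pct_2[c]


def adjust_p(
    p_values: np.ndarray, method: str = "bonferroni", m: int | None = None
) -> np.ndarray:
    """Multiple-testing adjustment with an explicit family size ``m``.

    ``m`` defaults to ``len(p_values)`` but may be larger (markers are
    screened per class while the family is all genes).  Bonferroni is
    ``min(1, p*m)``; BH is the step-up q-value with monotonicity enforced.
    """
    p = np.asarray(p_values, dtype=np.float64)
    finite = p[~np.isnan(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method != "bh":
        raise ValueError("method must be 'bonferroni' or 'bh'")
    nan = np.isnan(p)
    q = np.full_like(p, np.nan)
    pv = p[~nan]
    if pv.size:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, pv.size + 1)
        ranked = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
        out = np.empty_like(ranked)
        out[order] = ranked
        q[~nan] = out
    return q


def find_all_markers(
    matrix: SparseCounts,
    labels: Sequence,
    params: MarkerParams | None = None,
    prefilter: bool = True,
    continuity: bool = True,
) -> pd.DataFrame:
    """FindAllMarkers-equivalent table for every (class, gene) pair.

    Runs the one-vs-rest rank test, fold changes and detection fractions,
    adjusts p over the full gene family per class, and flags markers by
    ``log_fc > logfc_threshold and p_adj < alpha and max(pct) > min_pct``.

    With ``prefilter`` (the default), genes that fail the fold-change /
    detection screen for *every* class skip the rank test; they are still
    reported, with ``is_marker=False`` and ``p=NaN`` (or ``p=1`` for genes
    never detected anywhere, whose test is degenerate by construction).
    Skipping never changes an ``is_marker`` decision.
    """
    params = params or MarkerParams()
    if matrix.layer != "lognorm":
        raise ValueError("find_all_markers expects the lognorm layer")
    labels = np.asarray(labels)
    classes, codes = _factorize(labels)
    n_classes = len(classes)
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    n_genes = matrix.n_genes

    log_fc, pct_1, pct_2 = _fold_change_all(matrix.matrix, codes, n_classes, params)
    screen = (log_fc > params.logfc_threshold) & (
        np.maximum(pct_1, pct_2) > params.min_pct
    )

    p = np.full((n_classes, n_genes), np.nan)
    if prefilter:
        test_genes = np.flatnonzero(screen.any(axis=0))
    else:
        test_genes = np.arange(n_genes)
    if test_genes.size:
        sub = SparseCounts(
            sp.csc_matrix(matrix.matrix[:, test_genes]),
            matrix.gene_ids[test_genes],
            matrix.cell_ids,
            layer=matrix.layer,
        )
        res = wilcoxon_one_vs_rest(sub, labels, continuity=continuity)
        p[:, test_genes] = res.p
    # genes never detected in any cell: degenerate column, p = 1 by convention
    undetected = np.asarray((matrix.matrix != 0).sum(axis=0)).ravel() == 0
    p[:, undetected] = 1.0

    p_adj = np.vstack(
        [adjust_p(p[c], method=params.adjust_method, m=n_genes) for c in range(n_classes)]
    )
    with np.errstate(invalid="ignore"):
        is_marker = screen & (p_adj < params.alpha)  # NaN p_adj compares False

    out = pd.DataFrame(
        {
            "class": np.repeat(classes, n_genes),
            "gene": np.tile(matrix.gene_ids, n_classes),
            "log_fc": log_fc.ravel(),
            "pct_1": pct_1.ravel(),
            "pct_2": pct_2.ravel(),
            "p": p.ravel(),
            "p_adj": p_adj.ravel(),
            "is_marker": is_marker.ravel(),
        }
    )
    out.attrs["params"] = dataclasses.asdict(params)
    return out


def marker_counts(table: pd.DataFrame) -> pd.Series:
    """Markers per class (the headline output), indexed by class label."""
    return table.groupby("class", sort=False)["is_marker"].sum().astype(int)
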