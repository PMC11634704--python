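import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from markerdrift import SparseCounts, log_normalize
from markerdrift.synthetic_data import SyntheticAtlasSpec, generate_atlas


def make_counts(dense, layer="raw", gene_prefix="g", cell_prefix="c"):
    """SparseCounts from a dense cells x genes array."""
    dense = np.asarray(dense, dtype=float)
    n_cells, n_genes = dense.shape
    return SparseCounts(
        sp.csc_matrix(dense),
        np.array([f"{gene_prefix}{j}" for j in range(n_genes)], dtype=object),
        np.array([f"{cell_prefix}{i}" for i in range(n_cells)], dtype=object),
        layer=layer,
    )


def dense_wilcoxon_oracle(dense, labels, continuity=True):
    """Independent per-(gene, class) dense tie-corrected rank-sum p-values.

    Uses scipy's Mann-Whitney asymptotic path (midranks, tie-corrected
    variance, 0.5 continuity correction, two-sided normal approximation) on
    the densified column for every class split separately.
    """
    dense = np.asarray(dense, dtype=float)
    classes = list(dict.fromkeys(labels))  # first-appearance order
    labels = np.asarray(labels)
    p = np.empty((len(classes), dense.shape[1]))
    for ci, c in enumerate(classes):
        in_c = labels == c
        for g in range(dense.shape[1]):
            p[ci, g] = mannwhitneyu(
                dense[in_c, g],
                dense[~in_c, g],
                alternative="two-sided",
                method="asymptotic",
                use_continuity=continuity,
            ).pvalue
    return np.asarray(classes, dtype=object), p


@pytest.fixture(scope="session")
def small_atlas():
    """Three-type null atlas with planted markers (shift 2), ~600 cells."""
    spec = SyntheticAtlasSpec(
        n_genes=400,
        cell_types=("A", "B", "C"),
        markers_per_type=8,
        marker_log2_shift=2.0,
        n_donors_per_sex=3,
        sexes=("F",),
        cells_per_donor=200,
        regime="null",
        seed=42,
    )
    counts, cells, truth = generate_atlas(spec)
    return counts, cells, truth


@pytest.fixture(scope="session")
def small_atlas_lognorm(small_atlas):
    counts, cells, truth = small_atlas
    return log_normalize(counts), cells, truth


@pytest.fixture()
def qc_table():
    """Six-cell toy table exercising every QC threshold."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "n_genes_detected": [400, 3000, 5500, 1000, 1500, 2000],
            "total_umi": [900, 45000, 30000, 5000, 4000, 9000],
            "pct_mito": [2.0, 2.0, 2.0, 25.0, 3.0, 5.0],
        }
    )
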