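"""Age-related identity-drift analytics.

Donors of each sex are cut into 10 age deciles at donor-level age
quantiles; cells are then down-sampled so every (sex, cell type) keeps the
same number of cells in every decile, equalizing the power of the marker
test across ages.  On the balanced cells, markers are recomputed within
each decile independently (each cell type vs all other cells of that
decile) and the per-type marker count is regressed on the decile's mean
donor age — a declining count is the operational signature of identity
loss.  Complementary geometry on a PCA embedding distinguishes the two
candidate mechanisms: rising within-type distance-to-centroid (dispersion)
versus shrinking between-type centroid spread (convergence).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.decomposition import PCA

from .markers import MarkerParams, find_all_markers, marker_counts
from .sparse_io import SparseCounts

__all__ = [
    "DecileScheme",
    "assign_age_deciles",
    "balance_cells",
    "marker_trajectory",
    "composition_by_decile",
    "pca_embed",
    "dispersion_to_centroid",
    "convergence_distance",
    "centroid_spread",
    "regime_signature",
    "detect_regime",
    "aging_score",
    "assign_age_groups",
]


@dataclasses.dataclass
class DecileScheme:
    """Per-sex decile boundaries and membership.

    ``boundaries[sex]`` holds the 10%..90% donor-age quantiles (left-open /
    right-closed interior bins).  ``table`` has one row per (sex, decile)
    with donor ids, donor count, cell count and the decile midpoint age
    (mean donor age), the regression predictor.
    """

    boundaries: dict[str, np.ndarray]
    table: pd.DataFrame

    def midpoint(self, sex: str, decile: int) -> float:
        t = self.table
        row = t[(t["sex"] == sex) & (t["decile"] == decile)]
        return float(row["midpoint_age"].iloc[0])


def assign_age_deciles(
    cells: pd.DataFrame, n_bins: int = 10
) -> tuple[DecileScheme, pd.DataFrame]:
    """Assign each donor (hence each cell) to a per-sex age decile.

    Boundaries are the interior quantiles of *donor* ages per sex, so every
    cell of a donor lands in one decile and tied donor ages share a decile
    (populations may then be unequal).  Requires at least ``n_bins``
    distinct donor ages per sex.
    """
    donors = cells[["donor_id", "sex", "age_years"]].drop_duplicates("donor_id")
    if donors.groupby("donor_id")["age_years"].nunique().max() > 1:
        raise ValueError("a donor has inconsistent ages")
    boundaries: dict[str, np.ndarray] = {}
    rows = []
    decile_of_donor: dict[str, int] = {}
    for sex, grp in donors.groupby("sex"):
        ages = grp["age_years"].to_numpy(dtype=float)
        if len(ages) < n_bins:
            raise ValueError(
                f"only {len(ages)} donors of sex {sex!r}; need >= {n_bins} "
                f"(use fewer bins)"
            )
        if np.unique(ages).size < n_bins:
            raise ValueError(
                f"only {np.unique(ages).size} distinct donor ages for sex {sex!r}; "
                f"quantile bins are degenerate (use fewer bins)"
            )
        qs = np.quantile(ages, np.arange(1, n_bins) / n_bins)
        boundaries[sex] = qs
        # right-closed bins: decile d iff b_{d-1} < age <= b_d
        dec = np.searchsorted(qs, ages, side="left") + 1
        for donor, d in zip(grp["donor_id"], dec):
            decile_of_donor[donor] = int(d)
        for d in range(1, n_bins + 1):
            members = grp["donor_id"].to_numpy()[dec == d]
            if members.size == 0:
                continue
            m_ages = ages[dec == d]
            rows.append(
                {
                    "sex": sex,
                    "decile": d,
                    "donor_ids": list(members),
                    "n_donors": int(members.size),
                    "midpoint_age": float(m_ages.mean()),
                }
            )
    out = cells.copy()
    out["decile"] = out["donor_id"].map(decile_of_donor).astype(int)
    table = pd.DataFrame(rows)
    cell_counts = (
        out.groupby(["sex", "decile"], sort=True)["cell_id"].size().rename("n_cells")
    )
    table = table.merge(cell_counts.reset_index(), on=["sex", "decile"], how="left")
    table["n_cells"] = table["n_cells"].fillna(0).astype(int)
    return DecileScheme(boundaries, table), out


def balance_cells(cells: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Down-sample so each (sex, cell type) has equal cells in every decile.

    For each (sex, cell_type) unit, every decile retains ``m`` cells, the
    minimum decile count of that unit, sampled uniformly without
    replacement.  Units with an empty decile are dropped with a warning.
    Returns retained positional indices (sorted); deterministic given seed.
    """
    if "decile" not in cells:
        raise ValueError("run assign_age_deciles first")
    cells = cells.reset_index(drop=True)  # positional indices
    rng = np.random.default_rng(seed)
    deciles = np.sort(cells["decile"].unique())
    keep: list[np.ndarray] = []
    units = cells.groupby(["sex", "cell_type"], sort=True)
    for (sex, ctype), grp in units:
        counts = grp.groupby("decile").size().reindex(deciles, fill_value=0)
        if (counts == 0).any():
            warnings.warn(
                f"unit (sex={sex}, cell_type={ctype}) missing from some deciles; dropped"
            )
            continue
        m = int(counts.min())
        for d in deciles:
            pos = grp.index[grp["decile"] == d].to_numpy()
            pos = np.sort(pos)
            if len(pos) == m:
                keep.append(pos)
            else:
                keep.append(np.sort(rng.choice(pos, size=m, replace=False)))
    if not keep:
        return np.empty(0, dtype=int)
    return np.sort(np.concatenate(keep))


def marker_trajectory(
    matrix: SparseCounts,
    cells: pd.DataFrame,
    scheme: DecileScheme,
    params: MarkerParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-decile marker counts and their linear fit against age.

    ``cells`` must carry decile labels (and normally be balanced).  For
    each sex and decile, markers are found among that decile's cells only;
    deciles with a single cell type are skipped with a warning.  Returns
    (counts, fits): counts has one row per (sex, cell_type, decile) with
    ``n_markers`` and ``midpoint_age``; fits has the per-(sex, cell_type)
    OLS slope (markers per year), intercept and r-squared.
    """
    params = params or MarkerParams()
    if len(cells) != matrix.n_cells:
        raise ValueError("cells table must align row-for-row with the matrix")
    cells = cells.reset_index(drop=True)  # row i of the table <-> cell i
    count_rows = []
    for (sex, decile), grp in cells.groupby(["sex", "decile"], sort=True):
        types = grp["cell_type"].unique()
        if len(types) < 2:
            warnings.warn(f"decile {decile} ({sex}) has a single cell type; skipped")
            continue
        sub = matrix.subset_cells(grp.index.to_numpy())
        table = find_all_markers(sub, grp["cell_type"].to_numpy(), params=params)
        counts = marker_counts(table)
        mid = scheme.midpoint(sex, int(decile))
        for ctype, k in counts.items():
            count_rows.append(
                {
                    "sex": sex,
                    "cell_type": ctype,
                    "decile": int(decile),
                    "midpoint_age": mid,
                    "n_markers": int(k),
                }
            )
    counts_df = pd.DataFrame(count_rows)
    fit_rows = []
    for (sex, ctype), grp in counts_df.groupby(["sex", "cell_type"], sort=True):
        if len(grp) < 3:
            continue
        x = grp["midpoint_age"].to_numpy()
        y = grp["n_markers"].to_numpy(dtype=float)
        if np.allclose(y, y[0]) or np.allclose(x, x[0]):
            slope, intercept, r2 = 0.0, float(y.mean()), 0.0
        else:
            fit = linregress(x, y)
            slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
        fit_rows.append(
            {
                "sex": sex,
                "cell_type": ctype,
                "slope": float(slope),
                "intercept": float(intercept),
                "r_squared": float(r2),
            }
        )
    return counts_df, pd.DataFrame(fit_rows)


def composition_by_decile(cells: pd.DataFrame) -> pd.DataFrame:
    """Cell-type fractions per (sex, decile); computed before balancing."""
    if "decile" not in cells:
        raise ValueError("run assign_age_deciles first")
    counts = (
        cells.groupby(["sex", "decile", "cell_type"], sort=True)["cell_id"]
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["sex", "decile"])["n"].transform("sum")
    counts["fraction"] = counts["n"] / totals
    return counts


def pca_embed(
    matrix: SparseCounts,
    n_var_genes: int = 2000,
    n_components: int = 20,
    random_state: int = 0,
) -> np.ndarray:
    """Embed cells: top-variance genes, per-gene standardization, PCA.

    The ``n_var_genes`` genes with the highest variance of log-normalized
    expression are centered and unit-scaled, then projected onto the top
    ``n_components`` principal components.  Constant genes among the
    selection are dropped with a warning.  Component signs are fixed by
    making each component's largest-magnitude gene loading positive, so
    embeddings are reproducible.
    """
    if matrix.layer != "lognorm":
        raise ValueError("pca_embed expects the lognorm layer")
    m = matrix.matrix
    n = matrix.n_cells
    mean = np.asarray(m.mean(axis=0)).ravel()
    sq = np.asarray(m.multiply(m).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
    n_var_genes = min(n_var_genes, matrix.n_genes)
    top = np.sort(np.argsort(var, kind="stable")[::-1][:n_var_genes])
    constant = top[var[top] <= 1e-12]
    if constant.size:
        warnings.warn(f"dropping {constant.size} constant genes from PCA selection")
        top = top[var[top] > 1e-12]
    if n_components > min(len(top), n):
        raise ValueError("n_components exceeds usable genes or cells")
    x = np.asarray(m[:, top].todense())
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=random_state)
    scores = pca.fit_transform(x)
    flip = np.sign(
        pca.components_[np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    return scores * flip


def assign_age_groups(
    ages: np.ndarray, young_max: float = 40.0, old_min: float = 79.0
) -> np.ndarray:
    """Label cells young (< young_max), old (> old_min) or middle (excluded)."""
    ages = np.asarray(ages, dtype=float)
    out = np.full(ages.shape, "middle", dtype=object)
    out[ages < young_max] = "young"
    out[ages > old_min] = "old"
    return out


def dispersion_to_centroid(embedding: np.ndarray, index: np.ndarray, dims: int = 10) -> dict:
    """Mean Euclidean distance of a subset's cells to its own centroid.

    Uses the first ``dims`` embedding dimensions.  Returns mean, standard
    error (0 with ``se_undefined=True`` when n = 1) and n.
    """
    index = np.asarray(index)
    if index.dtype == bool:
        index = np.flatnonzero(index)
    if index.size == 0:
        raise ValueError("empty subset")
    x = embedding[index, :dims]
    centroid = x.mean(axis=0)
    d = np.linalg.norm(x - centroid, axis=1)
    n = len(d)
    se_undef = n < 2
    se = 0.0 if se_undef else float(d.std(ddof=1) / np.sqrt(n))
    return {"mean": float(d.mean()), "se": se, "n": n, "se_undefined": se_undef}


def convergence_distance(
    embedding: np.ndarray,
    cell_types: Sequence,
    index: np.ndarray,
    dims: int = 10,
) -> pd.DataFrame:
    """Distance of each cell to the *global* centroid of a group of cells.

    One centroid is computed over all the group's cells (all types pooled);
    per-type and overall mean/SE of the distances are returned.  This is
    the between-subsets quantity of the convergence analysis.
    """
    index = np.asarray(index)
    if index.dtype == bool:
        index = np.flatnonzero(index)
    types = np.asarray(cell_types)[index]
    if np.unique(types).size < 2:
        raise ValueError("need >= 2 cell types in the group")
    x = embedding[index, :dims]
    centroid = x.mean(axis=0)
    d = np.linalg.norm(x - centroid, axis=1)
    rows = []
    for label in ["__all__", *sorted(map(str, np.unique(types)))]:
        sel = np.ones(len(d), bool) if label == "__all__" else (types == label)
        dd = d[sel]
        se = float(dd.std(ddof=1) / np.sqrt(len(dd))) if len(dd) > 1 else 0.0
        rows.append(
            {"cell_type": label, "mean": float(dd.mean()), "se": se, "n": int(len(dd))}
        )
    return pd.DataFrame(rows)


def centroid_spread(
    embedding: np.ndarray, cell_types: Sequence, index: np.ndarray, dims: int = 10
) -> float:
    """Mean distance of per-type centroids to the group's global centroid.

    A pure between-type separation summary (insensitive to within-type
    noise), used to discriminate the dispersion and convergence regimes.
    """
    index = np.asarray(index)
    if index.dtype == bool:
        index = np.flatnonzero(index)
    types = np.asarray(cell_types)[index]
    x = embedding[index, :dims]
    global_c = x.mean(axis=0)
    cents = np.vstack([x[types == t].mean(axis=0) for t in np.unique(types)])
    return float(np.linalg.norm(cents - global_c, axis=1).mean())


def regime_signature(
    embedding: np.ndarray,
    cell_types: Sequence,
    young: np.ndarray,
    old: np.ndarray,
    dims: int = 10,
) -> dict:
    """Young-vs-old geometry summary used to discriminate drift mechanisms.

    Returns per-type within-subset mean distances for both age groups, the
    overall per-cell distance to the group's global centroid (the
    between-subsets quantity), and the per-type centroid spread.
    """
    types = np.asarray(cell_types)
    out: dict = {"within": {}, "between": {}, "spread": {}}
    for name, sel in (("young", np.asarray(young)), ("old", np.asarray(old))):
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        grp_types = types[sel]
        out["within"][name] = {
            str(t): dispersion_to_centroid(
                embedding, sel[grp_types == t], dims=dims
            )["mean"]
            for t in np.unique(grp_types)
        }
        conv = convergence_distance(embedding, types, sel, dims=dims)
        out["between"][name] = float(
            conv.loc[conv["cell_type"] == "__all__", "mean"].iloc[0]
        )
        out["spread"][name] = centroid_spread(embedding, types, sel, dims=dims)
    return out


def detect_regime(signature: dict, rel_tol: float = 0.10) -> str:
    """Classify a young/old geometry signature as dispersion or convergence.

    Dispersion: every cell type's within-subset distance grows with age
    while the between-subsets distance moves by less than ``rel_tol``.
    Convergence: the between-subsets distance shrinks by more than
    ``rel_tol`` without a uniform within-subset increase.  Anything else
    is ``"ambiguous"``.
    """
    wy, wo = signature["within"]["young"], signature["within"]["old"]
    shared = sorted(set(wy) & set(wo))
    all_up = all(wo[t] > wy[t] for t in shared)
    by, bo = signature["between"]["young"], signature["between"]["old"]
    bchange = (bo - by) / by
    if all_up and abs(bchange) < rel_tol:
        return "dispersion"
    if bchange < -rel_tol and not all_up:
        return "convergence"
    return "ambiguous"


def aging_score(
    lognorm: SparseCounts,
    cells: pd.DataFrame,
    gene_list: Sequence[str],
    method: str = "z_mean",
    raw: SparseCounts | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-cell signature score over a predefined gene list.

    ``z_mean`` (default): per gene, Z-normalize log-normalized expression
    across all cells, then average over the list genes per cell.
    ``umi_ratio``: fraction of the cell's raw UMIs on list genes (requires
    the raw layer; in [0, 1] and independent of normalization parameters).
    Missing list genes are dropped with a warning; an empty intersection is
    an error.  Returns the per-cell table and mean-score summaries grouped
    by cell type and (when present) by decile.
    """
    gene_list = list(dict.fromkeys(gene_list))
    pos_of = {g: i for i, g in enumerate(lognorm.gene_ids)}
    present = [g for g in gene_list if g in pos_of]
    missing = len(gene_list) - len(present)
    if not present:
        raise ValueError("no gene of the list is present in the matrix")
    if missing:
        warnings.warn(f"{missing} list genes absent from the matrix; dropped")
    idx = np.array([pos_of[g] for g in present])

    if method == "z_mean":
        x = np.asarray(lognorm.matrix[:, idx].todense())
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # constant genes contribute 0
        score = ((x - mu) / sd).mean(axis=1)
    elif method == "umi_ratio":
        if raw is None or raw.layer != "raw":
            raise ValueError("umi_ratio needs the raw layer")
        sub = np.asarray(raw.matrix[:, idx].sum(axis=1)).ravel()
        tot = raw.cell_totals()
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(tot > 0, sub / tot, 0.0)
    else:
        raise ValueError("method must be 'z_mean' or 'umi_ratio'")

    per_cell = cells[["cell_id", "cell_type"]].copy()
    if "decile" in cells:
        per_cell["decile"] = cells["decile"].to_numpy()
    per_cell["score"] = score
    summaries = {
        "by_cell_type": per_cell.groupby("cell_type")["score"].agg(["mean", "std", "count"]).reset_index()
    }
    if "decile" in per_cell:
        summaries["by_decile"] = (
            per_cell.groupby("decile")["score"].agg(["mean", "std", "count"]).reset_index()
        )
    return per_cell, summaries
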