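import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from markerdrift import (
    SparseCounts,
    aging_score,
    assign_age_deciles,
    assign_age_groups,
    balance_cells,
    centroid_spread,
    composition_by_decile,
    convergence_distance,
    dispersion_to_centroid,
    log_normalize,
    marker_trajectory,
    pca_embed,
)
from markerdrift.synthetic_data import SyntheticAtlasSpec, generate_atlas

from conftest import make_counts


def cells_frame(donor_ages, cells_per_donor=4, sexes=("F",), types=("T", "B")):
    rows = []
    i = 0
    for sex in sexes:
        for d, age in enumerate(donor_ages):
            for c in range(cells_per_donor):
                rows.append(
                    {
                        "cell_id": f"c{i}",
                        "donor_id": f"{sex}{d}",
                        "cell_type": types[i % len(types)],
                        "age_years": age,
                        "sex": sex,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


class TestAgeDeciles:
    def test_even_split_with_distinct_ages(self):
        cells = cells_frame(donor_ages=np.arange(18, 118), sexes=("F", "M"))
        scheme, out = assign_age_deciles(cells)
        per = out.drop_duplicates("donor_id").groupby(["sex", "decile"]).size()
        assert (per == 10).all()
        assert len(scheme.table) == 20  # 10 deciles x 2 sexes

    def test_decile_is_donor_level(self):
        cells = cells_frame(donor_ages=np.arange(20, 80, 6))
        _, out = assign_age_deciles(cells)
        assert (out.groupby("donor_id")["decile"].nunique() == 1).all()

    def test_tied_ages_share_decile(self):
        ages = np.r_[np.arange(25), np.full(5, 50.0)]
        cells = cells_frame(donor_ages=ages)
        _, out = assign_age_deciles(cells)
        tied = out[out["age_years"] == 50.0]
        assert tied["decile"].nunique() == 1

    def test_degenerate_ages_error(self):
        cells = cells_frame(donor_ages=np.full(20, 50.0))
        with pytest.raises(ValueError, match="distinct"):
            assign_age_deciles(cells)

    def test_too_few_donors_error(self):
        cells = cells_frame(donor_ages=np.arange(30, 35))
        with pytest.raises(ValueError, match="fewer bins"):
            assign_age_deciles(cells)

    def test_midpoint_is_mean_donor_age(self):
        cells = cells_frame(donor_ages=np.arange(18, 118))
        scheme, out = assign_age_deciles(cells)
        d1 = out[(out["decile"] == 1)].drop_duplicates("donor_id")
        assert scheme.midpoint("F", 1) == pytest.approx(d1["age_years"].mean())


class TestBalanceCells:
    @pytest.fixture()
    def decile_cells(self):
        rng = np.random.default_rng(0)
        cells = cells_frame(
            donor_ages=np.arange(18, 98, 2), cells_per_donor=12, types=("T", "B", "NK")
        )
        # drop a random 25% so decile counts are genuinely unequal
        keep = rng.random(len(cells)) > 0.25
        _, out = assign_age_deciles(cells[keep].reset_index(drop=True))
        return out

    def test_counts_equalized(self, decile_cells):
        keep = balance_cells(decile_cells, seed=1)
        bal = decile_cells.iloc[keep]
        counts = bal.groupby(["sex", "cell_type", "decile"]).size().unstack()
        assert (counts.nunique(axis=1) == 1).all()

    def test_min_rule(self, decile_cells):
        keep = balance_cells(decile_cells, seed=1)
        bal = decile_cells.iloc[keep]
        orig = decile_cells.groupby(["sex", "cell_type", "decile"]).size()
        new = bal.groupby(["sex", "cell_type", "decile"]).size()
        for (sex, ct), grp in orig.groupby(level=[0, 1]):
            assert set(new.loc[sex, ct]) == {grp.min()}

    def test_deterministic_given_seed(self, decile_cells):
        a = balance_cells(decile_cells, seed=3)
        b = balance_cells(decile_cells, seed=3)
        c = balance_cells(decile_cells, seed=4)
        assert np.array_equal(a, b)
        assert len(a) == len(c)  # same counts under any seed
        assert not np.array_equal(a, c)

    def test_already_balanced_is_identity(self):
        cells = cells_frame(donor_ages=np.arange(18, 118), cells_per_donor=2)
        _, out = assign_age_deciles(cells)
        keep = balance_cells(out, seed=0)
        assert len(keep) == len(out)

    def test_empty_decile_drops_unit(self):
        cells = cells_frame(donor_ages=np.arange(18, 118), cells_per_donor=2)
        _, out = assign_age_deciles(cells)
        # remove all cells of one type from decile 1
        out = out[~((out["decile"] == 1) & (out["cell_type"] == "T"))]
        with pytest.warns(UserWarning, match="missing"):
            keep = balance_cells(out.reset_index(drop=True), seed=0)
        assert not (out.reset_index(drop=True).iloc[keep]["cell_type"] == "T").any()


def test_composition_fractions_sum_to_one():
    cells = cells_frame(donor_ages=np.arange(18, 118), cells_per_donor=4)
    _, out = assign_age_deciles(cells)
    comp = composition_by_decile(out)
    sums = comp.groupby(["sex", "decile"])["fraction"].sum()
    assert np.allclose(sums, 1.0)
    # alternating assignment -> 50/50 everywhere
    assert np.allclose(comp["fraction"], 0.5)


def test_composition_recovers_planted_replacement():
    spec = SyntheticAtlasSpec(
        n_genes=60,
        cell_types=("naive", "memory"),
        markers_per_type=5,
        n_donors_per_sex=30,
        sexes=("F",),
        cells_per_donor=60,
        type_proportions=([0.8, 0.2], [0.2, 0.8]),
        seed=5,
    )
    _, cells, _ = generate_atlas(spec)
    _, out = assign_age_deciles(cells)
    comp = composition_by_decile(out)
    naive = comp[comp["cell_type"] == "naive"].sort_values("decile")
    rho = np.corrcoef(naive["decile"], naive["fraction"])[0, 1]
    assert rho < -0.8  # strong monotone decline of the naive fraction


class TestPCAEmbed:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        dense = np.c_[t, 2 * t] + 5.0
        ln = make_counts(np.abs(dense), layer="lognorm")
        emb = pca_embed(ln, n_var_genes=2, n_components=2)
        # all variance on the first component
        assert emb[:, 1] == pytest.approx(0.0, abs=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        dense = rng.gamma(2, size=(40, 12))
        ln = make_counts(dense, layer="lognorm")
        emb = pca_embed(ln, n_var_genes=10, n_components=3)
        perm = rng.permutation(40)
        emb_p = pca_embed(ln.subset_cells(perm), n_var_genes=10, n_components=3)
        assert np.allclose(emb[perm], emb_p, atol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        dense = rng.gamma(2, size=(30, 6))
        ln = make_counts(dense, layer="lognorm")
        emb = pca_embed(ln, n_var_genes=6, n_components=6)
        x = dense.copy()
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        # distances are preserved by a complete orthonormal rotation
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(emb), pdist(x), atol=1e-8)

    def test_constant_gene_dropped(self):
        dense = np.c_[np.ones(20), np.random.default_rng(3).gamma(2, size=(20, 3))]
        ln = make_counts(dense, layer="lognorm")
        with pytest.warns(UserWarning, match="constant"):
            emb = pca_embed(ln, n_var_genes=4, n_components=2)
        assert emb.shape == (20, 2)


class TestDistances:
    def test_identical_cells_zero_distance(self):
        emb = np.ones((5, 10))
        d = dispersion_to_centroid(emb, np.arange(5))
        assert d["mean"] == 0.0

    def test_two_point_symmetry(self):
        emb = np.zeros((2, 10))
        emb[0, 0], emb[1, 0] = 1.0, -1.0
        d = dispersion_to_centroid(emb, np.arange(2))
        assert d["mean"] == pytest.approx(1.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(30, 10))
        d1 = dispersion_to_centroid(emb, np.arange(30))
        d2 = dispersion_to_centroid(2 * emb, np.arange(30))
        assert d2["mean"] == pytest.approx(2 * d1["mean"])

    def test_singleton_se_flagged(self):
        d = dispersion_to_centroid(np.random.default_rng(5).normal(size=(3, 10)),
                                   np.array([0]))
        assert d["se"] == 0.0 and d["se_undefined"]

    def test_convergence_two_types_symmetric(self):
        emb = np.zeros((40, 10))
        emb[:20, 0], emb[20:, 0] = 3.0, -3.0
        types = np.array(["a"] * 20 + ["b"] * 20)
        res = convergence_distance(emb, types, np.arange(40))
        by_type = res.set_index("cell_type")["mean"]
        assert by_type["a"] == pytest.approx(3.0)
        assert by_type["b"] == pytest.approx(3.0)
        assert by_type["__all__"] == pytest.approx(3.0)
        assert centroid_spread(emb, types, np.arange(40)) == pytest.approx(3.0)

    def test_coincident_types_zero(self):
        emb = np.ones((10, 10))
        types = np.array(["a", "b"] * 5)
        res = convergence_distance(emb, types, np.arange(10))
        assert np.allclose(res["mean"], 0.0)


def test_age_group_assignment_boundaries():
    groups = assign_age_groups(np.array([25.0, 40.0, 60.0, 79.0, 85.0]))
    assert list(groups) == ["young", "middle", "middle", "middle", "old"]


class TestAgingScore:
    @pytest.fixture()
    def toy(self):
        raw = make_counts([[4, 0, 6], [0, 2, 0], [1, 1, 1]])
        ln = log_normalize(raw)
        cells = pd.DataFrame(
            {"cell_id": ["c0", "c1", "c2"], "cell_type": ["T", "T", "B"]}
        )
        return raw, ln, cells

    def test_umi_ratio_extremes(self, toy):
        raw, ln, cells = toy
        per_cell, _ = aging_score(ln, cells, ["g0", "g2"], method="umi_ratio", raw=raw)
        # cell c0: all UMIs on list genes -> 1; cell c1: none -> 0
        assert per_cell["score"].iloc[0] == pytest.approx(1.0)
        assert per_cell["score"].iloc[1] == pytest.approx(0.0)
        assert per_cell["score"].between(0, 1).all()

    def test_z_mean_zero_at_population_mean(self):
        dense = np.array([[1.0, 2.0], [3.0, 6.0], [2.0, 4.0]])  # row 2 is the mean
        ln = make_counts(dense, layer="lognorm")
        cells = pd.DataFrame({"cell_id": ["a", "b", "c"], "cell_type": ["T"] * 3})
        per_cell, _ = aging_score(ln, cells, ["g0", "g1"], method="z_mean")
        assert per_cell["score"].iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_missing_genes_warn_empty_errors(self, toy):
        raw, ln, cells = toy
        with pytest.warns(UserWarning, match="absent"):
            aging_score(ln, cells, ["g0", "nope"], method="z_mean")
        with pytest.raises(ValueError):
            aging_score(ln, cells, ["nope"], method="z_mean")

    def test_umi_ratio_normalization_invariant(self, toy):
        raw, ln, cells = toy
        ln_b = log_normalize(raw, scale_factor=1e6)
        a, _ = aging_score(ln, cells, ["g0"], method="umi_ratio", raw=raw)
        b, _ = aging_score(ln_b, cells, ["g0"], method="umi_ratio", raw=raw)
        assert np.allclose(a["score"], b["score"])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dispersion_dilutes_marker_counts(seed):
    """More within-type dispersion -> fewer markers at fixed thresholds,
    monotone across three dispersion levels (the mechanism linking rising
    heterogeneity to the loss of detectable identity)."""
    from markerdrift import find_all_markers, marker_counts

    totals = []
    for phi in (0.3, 0.9, 1.8):
        spec = SyntheticAtlasSpec(
            n_genes=300, cell_types=("A", "B", "C"), markers_per_type=40,
            marker_log2_shift=1.5, base_phi=phi, n_donors_per_sex=3,
            sexes=("F",), cells_per_donor=100, regime="null", seed=seed,
        )
        counts, cells, _ = generate_atlas(spec)
        table = find_all_markers(log_normalize(counts), cells["cell_type"].to_numpy())
        totals.append(int(marker_counts(table).sum()))
    assert totals[0] > totals[1] > totals[2]


def test_trajectory_constant_response_gives_zero_slope():
    """One decile's cells replicated as all ten deciles: slope exactly 0."""
    rng = np.random.default_rng(6)
    block = rng.poisson(2.0, size=(40, 30)).astype(float)
    block[:20, :5] += 6  # type T markers
    dense = np.tile(block, (10, 1))
    counts = make_counts(dense)
    rows = []
    for d in range(10):
        for i in range(40):
            rows.append(
                {
                    "cell_id": f"c{d}_{i}",
                    "donor_id": f"F{d}",
                    "cell_type": "T" if i < 20 else "B",
                    "age_years": 20.0 + 7 * d,
                    "sex": "F",
                    "decile": d + 1,
                }
            )
    cells = pd.DataFrame(rows)
    counts.cell_ids = np.array([r["cell_id"] for r in rows], dtype=object)
    scheme_table = pd.DataFrame(
        {
            "sex": "F",
            "decile": np.arange(1, 11),
            "donor_ids": [[f"F{d}"] for d in range(10)],
            "n_donors": 1,
            "midpoint_age": 20.0 + 7 * np.arange(10),
            "n_cells": 40,
        }
    )
    from markerdrift.identity_drift import DecileScheme

    scheme = DecileScheme({"F": np.array([])}, scheme_table)
    ln = log_normalize(counts)
    counts_df, fits = marker_trajectory(ln, cells, scheme)
    piv = counts_df.pivot(index="decile", columns="cell_type", values="n_markers")
    assert (piv.nunique() == 1).all()
    assert np.allclose(fits["slope"], 0.0)
    assert (piv["T"] > 0).all()  # the planted markers are actually detected
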