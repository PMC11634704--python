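"""Synthetic sparse scRNA-like atlases with known ground truth.

The generator realizes the two competing explanations for age-related loss
of cell-type identity as explicit simulation regimes:

* ``dispersion`` — within-cell-type heterogeneity is multiplied by an
  age-dependent factor (young -> old): both the negative-binomial
  overdispersion and the magnitude of latent, gene-correlated cell-state
  fluctuations grow with age, widening each type's expression cloud while
  type means stay put;
* ``convergence`` — the marker-gene mean shift that separates the types is
  shrunk toward the global mean with age, moving type centroids together
  while within-type noise stays put;
* ``null`` — neither law is active.

Counts are gamma-Poisson (negative binomial) with per-gene base means drawn
lognormally and rescaled so the expected zero fraction hits
``target_sparsity``; each cell carries a lognormal library-size factor, and
each cell type owns a disjoint block of marker genes whose mean is shifted
up by ``marker_log2_shift`` log2 units in member cells.  Randomness is
split hierarchically (structure / donor / cell), so adding donors or cells
never perturbs the draws of existing ones.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .sparse_io import SparseCounts, attach_qc_stats

__all__ = [
    "SyntheticAtlasSpec",
    "GroundTruth",
    "generate_atlas",
    "generate_random_sparse",
]


def _linear_law(age: float, age_range: tuple[float, float], lo: float, hi: float) -> float:
    """Linear interpolation lo -> hi across the age range, clipped outside it."""
    a0, a1 = age_range
    t = np.clip((age - a0) / (a1 - a0), 0.0, 1.0)
    return lo + (hi - lo) * t


@dataclasses.dataclass
class SyntheticAtlasSpec:
    """Full parameterization of one synthetic atlas.

    ``dispersion_k`` and ``convergence_c`` give the (young, old) endpoints
    of the active regime's linear age law; only the law selected by
    ``regime`` is applied.  ``donor_ages`` may pin explicit donor ages per
    sex (e.g. a young/old two-block pyramid); otherwise ages are uniform
    over ``age_range``.  ``type_proportions`` optionally gives (young, old)
    cell-type probability vectors that are linearly interpolated with donor
    age, to plant compositional drift.
    """

    n_genes: int = 2000
    cell_types: tuple[str, ...] = ("T_naive", "T_effector", "NK")
    markers_per_type: int = 10
    marker_log2_shift: float = 2.0
    n_donors_per_sex: int = 20
    sexes: tuple[str, ...] = ("F", "M")
    age_range: tuple[float, float] = (18.0, 90.0)
    donor_ages: dict[str, Sequence[float]] | None = None
    cells_per_donor: int = 100
    base_phi: float = 0.4
    regime: str = "null"
    dispersion_k: tuple[float, float] = (1.0, 3.0)
    convergence_c: tuple[float, float] = (1.0, 0.3)
    type_proportions: tuple[Sequence[float], Sequence[float]] | None = None
    target_sparsity: float = 0.9
    library_sigma: float = 0.3
    base_mean_sigma: float = 1.0
    state_factors: int = 3
    state_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("null", "dispersion", "convergence"):
            raise ValueError("regime must be null, dispersion or convergence")
        if self.markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("not enough genes for disjoint marker blocks")
        if not (0 < self.target_sparsity < 1):
            raise ValueError("target_sparsity must be in (0, 1)")
        if self.base_phi <= 0 or self.marker_log2_shift < 0:
            raise ValueError("base_phi must be positive, shift non-negative")

    # regime laws ------------------------------------------------------
    def phi_at(self, age: float) -> float:
        if self.regime == "dispersion":
            return self.base_phi * _linear_law(age, self.age_range, *self.dispersion_k)
        return self.base_phi

    def state_sigma_at(self, age: float) -> float:
        """Log-sd of the coherent cell-state fluctuation at the given age.

        In the dispersion regime the age law scales this alongside the NB
        overdispersion: independent per-gene count noise alone is nearly
        invisible in a low-dimensional embedding (it averages out across
        genes), so within-type transcriptome spread is carried chiefly by
        these gene-correlated state factors.
        """
        if self.regime == "dispersion":
            return self.state_sigma * _linear_law(age, self.age_range, *self.dispersion_k)
        return self.state_sigma

    def shift_at(self, age: float) -> float:
        if self.regime == "convergence":
            return self.marker_log2_shift * _linear_law(
                age, self.age_range, *self.convergence_c
            )
        return self.marker_log2_shift

    def proportions_at(self, age: float) -> np.ndarray:
        k = len(self.cell_types)
        if self.type_proportions is None:
            return np.full(k, 1.0 / k)
        young, old = (np.asarray(v, dtype=float) for v in self.type_proportions)
        p = _linear_law(age, self.age_range, 0.0, 1.0)
        mix = (1 - p) * young + p * old
        return mix / mix.sum()


@dataclasses.dataclass
class GroundTruth:
    """Planted structure emitted alongside every atlas."""

    marker_genes: dict[str, list[str]]
    donors: pd.DataFrame
    spec: dict

    def marker_of(self) -> dict[str, str]:
        """gene id -> owning cell type."""
        return {g: t for t, gs in self.marker_genes.items() for g in gs}


def _nb_zero_fraction(mu: np.ndarray, phi: float) -> float:
    """Expected zero probability of NB(mu, phi), averaged over genes."""
    return float(np.mean((1.0 + phi * mu) ** (-1.0 / phi)))


def _calibrate_scale(base: np.ndarray, phi: float, target: float) -> float:
    """Scalar s with mean_g P0(s * base_g) = target sparsity, by bisection."""
    lo, hi = 1e-8, 1e8
    if not (_nb_zero_fraction(base * lo, phi) > target > _nb_zero_fraction(base * hi, phi)):
        raise ValueError(
            f"target sparsity {target} unreachable for this mean/dispersion recipe"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _nb_zero_fraction(base * mid, phi) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _donor_stream(seed: int, sex_idx: int, donor_idx: int) -> np.random.SeedSequence:
    # explicit spawn keys: donor streams are independent of how many donors exist
    return np.random.SeedSequence([int(seed), 1 + sex_idx, donor_idx])


def generate_atlas(
    spec: SyntheticAtlasSpec,
) -> tuple[SparseCounts, pd.DataFrame, GroundTruth]:
    """Sample one atlas: raw counts, per-cell annotation table, ground truth.

    Deterministic given ``spec.seed``.  The annotation table carries
    cell_id, donor_id, cell_type, age_years, sex, pct_mito (0; mitochondrial
    contamination is not modeled) plus QC stats computed from the matrix.
    """
    struct_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    gene_ids = np.array([f"G{i:05d}" for i in range(spec.n_genes)], dtype=object)
    base = struct_rng.lognormal(mean=0.0, sigma=spec.base_mean_sigma, size=spec.n_genes)
    scale = _calibrate_scale(base, spec.base_phi, spec.target_sparsity)
    base = base * scale

    perm = struct_rng.permutation(spec.n_genes)
    marker_genes: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    # markers are planted on detectably expressed genes: floor their base
    # mean at the 60th percentile so the planted shift is observable at all
    floor = np.quantile(base, 0.6)
    for t, name in enumerate(spec.cell_types):
        block = perm[t * spec.markers_per_type : (t + 1) * spec.markers_per_type]
        marker_idx[name] = np.sort(block)
        marker_genes[name] = [str(gene_ids[i]) for i in np.sort(block)]
        base[marker_idx[name]] = np.maximum(base[marker_idx[name]], floor)

    # gene loadings of the latent cell-state factors (coherent within-type
    # heterogeneity); rows have unit expected squared norm.  Marker genes
    # carry no state loading: identity programs are modeled as tightly
    # regulated, so state noise widens the type cloud without moving or
    # blurring the type centroids themselves.
    q = spec.state_factors
    loadings = struct_rng.normal(0.0, 1.0 / np.sqrt(q), size=(spec.n_genes, q))
    for idx in marker_idx.values():
        loadings[idx] = 0.0
    row_sq = (loadings**2).sum(axis=1)

    donor_rows = []
    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    rows_v: list[np.ndarray] = []
    cell_rows = []
    cell_counter = 0
    for s_idx, sex in enumerate(spec.sexes):
        fixed = None if spec.donor_ages is None else list(spec.donor_ages[sex])
        n_donors = spec.n_donors_per_sex if fixed is None else len(fixed)
        for d in range(n_donors):
            d_ss = _donor_stream(spec.seed, s_idx, d)
            d_rng = np.random.default_rng(d_ss)
            age = float(d_rng.uniform(*spec.age_range)) if fixed is None else float(fixed[d])
            donor_id = f"{sex}{d:03d}"
            donor_rows.append({"donor_id": donor_id, "sex": sex, "age_years": age})
            phi = spec.phi_at(age)
            sig_state = spec.state_sigma_at(age)
            boost = 2.0 ** spec.shift_at(age)
            probs = spec.proportions_at(age)
            cell_streams = d_ss.spawn(spec.cells_per_donor)
            for c_ss in cell_streams:
                c_rng = np.random.default_rng(c_ss)
                lib = float(np.exp(c_rng.normal(0.0, spec.library_sigma)))
                t_idx = int(c_rng.choice(len(spec.cell_types), p=probs))
                t_name = spec.cell_types[t_idx]
                mu = base * lib
                if sig_state > 0:
                    eps = c_rng.normal(0.0, sig_state, size=q)
                    # mean-corrected lognormal state factor: E[mu] unchanged
                    mu = mu * np.exp(loadings @ eps - 0.5 * sig_state**2 * row_sq)
                else:
                    mu = mu.copy()
                if boost != 1.0:
                    mu[marker_idx[t_name]] *= boost
                lam = c_rng.gamma(shape=1.0 / phi, scale=mu * phi)
                counts = c_rng.poisson(lam)
                nz = np.flatnonzero(counts)
                rows_i.append(np.full(nz.size, cell_counter))
                rows_j.append(nz)
                rows_v.append(counts[nz])
                cell_rows.append(
                    {
                        "cell_id": f"cell{cell_counter:06d}",
                        "donor_id": donor_id,
                        "cell_type": t_name,
                        "age_years": age,
                        "sex": sex,
                        "pct_mito": 0.0,
                    }
                )
                cell_counter += 1

    i = np.concatenate(rows_i) if rows_i else np.empty(0, int)
    j = np.concatenate(rows_j) if rows_j else np.empty(0, int)
    v = np.concatenate(rows_v) if rows_v else np.empty(0, int)
    matrix = sp.csc_matrix(
        (v.astype(np.float64), (i, j)), shape=(cell_counter, spec.n_genes)
    )
    cells = pd.DataFrame(cell_rows)
    counts = SparseCounts(
        matrix, gene_ids, cells["cell_id"].to_numpy(dtype=object), layer="raw"
    )
    cells = attach_qc_stats(counts, cells)
    truth = GroundTruth(
        marker_genes=marker_genes,
        donors=pd.DataFrame(donor_rows),
        spec=dataclasses.asdict(spec),
    )
    return counts, cells, truth


def generate_random_sparse(
    n_genes: int,
    n_cells: int,
    density: float,
    n_classes: int,
    seed: int,
    max_value: int = 10,
) -> tuple[SparseCounts, np.ndarray]:
    """Uniform random sparse count matrix with uniform class labels.

    Nonzeros are placed uniformly without replacement at exactly
    ``round(density * n_genes * n_cells)`` positions with integer values in
    ``1..max_value``; labels are uniform over ``n_classes`` classes.  Used
    for oracle fuzzing of the rank engine.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    total = n_genes * n_cells
    nnz = int(round(density * total))
    flat = rng.choice(total, size=nnz, replace=False)
    cell_i, gene_j = np.divmod(flat, n_genes)
    values = rng.integers(1, max_value + 1, size=nnz).astype(np.float64)
    matrix = sp.csc_matrix((values, (cell_i, gene_j)), shape=(n_cells, n_genes))
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"cell{i:06d}" for i in range(n_cells)], dtype=object)
    labels = np.array([f"class{k}" for k in rng.integers(0, n_classes, size=n_cells)])
    return SparseCounts(matrix, gene_ids, cell_ids, layer="raw"), labels
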