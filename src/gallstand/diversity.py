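"""Diversity and apparency covariates at plot and neighborhood scales.

The explanatory variables of the damage analysis are species richness,
Shannon diversity and host (chestnut) proportion — the latter two weighted
by relative stem basal area — plus taxonomic diversity Δ (the abundance-
weighted average Linnaean path length between pairs of individuals, after
Clarke & Warwick) and the plot-mean incidence of native cynipid galls on
oak leaves, a proxy for shared-parasitoid abundance.

The built-in taxonomy covers the five stand species: Castanea sativa,
Quercus cerris, Q. ilex, Q. petraea (all Fagaceae) and Ostrya carpinifolia
(Betulaceae); all five are Fagales.  With unit step lengths per Linnaean
level the three oaks are congeners (pairwise distance 2), any oak is at
distance 4 from chestnut, and O. carpinifolia is at distance 6 from every
Fagaceae — so the three Quercus are exactly equidistant from both C. sativa
and O. carpinifolia, a degeneracy of this classification that the index
inherits by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from gallstand.crown_damage import leaf_gall_incidence

__all__ = [
    "DEFAULT_TAXONOMY",
    "HOST_SPECIES",
    "OAK_SPECIES",
    "basal_area",
    "shannon_index",
    "taxonomic_distance_matrix",
    "taxonomic_diversity",
    "oak_gall_covariate",
    "plot_covariates",
    "neighborhood_covariates",
]

HOST_SPECIES = "CS"
OAK_SPECIES = ("QC", "QI", "QP")

#: species code -> (species, genus, family, order)
DEFAULT_TAXONOMY = pd.DataFrame(
    [
        ("CS", "Castanea sativa", "Castanea", "Fagaceae", "Fagales"),
        ("QC", "Quercus cerris", "Quercus", "Fagaceae", "Fagales"),
        ("QI", "Quercus ilex", "Quercus", "Fagaceae", "Fagales"),
        ("QP", "Quercus petraea", "Quercus", "Fagaceae", "Fagales"),
        ("OC", "Ostrya carpinifolia", "Ostrya", "Betulaceae", "Fagales"),
    ],
    columns=["code", "species", "genus", "family", "order"],
).set_index("code")


def basal_area(dbh_cm) -> np.ndarray:
    """Stem basal area in m² from diameter at breast height in cm."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh must be positive")
    return np.pi * (dbh / 200.0) ** 2


def shannon_index(shares) -> float:
    """Shannon diversity H' = −Σ p_i ln p_i on abundance shares."""
    p = np.asarray(shares, dtype=float)
    if p.size == 0:
        raise ValueError("empty community")
    if np.any(p < 0):
        raise ValueError("negative abundance share")
    total = p.sum()
    if total <= 0:
        raise ValueError("all shares zero")
    if not np.isclose(total, 1.0):
        warnings.warn("shares do not sum to 1; renormalizing", stacklevel=2)
        p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def taxonomic_distance_matrix(
    species: list[str],
    taxonomy: pd.DataFrame | None = None,
    step_lengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Pairwise Linnaean path lengths between species.

    The distance between two species is twice the weighted number of rank
    steps (species→genus→family→order) up to their lowest shared rank;
    species sharing no rank sit at twice the full path.  Symmetric, zero on
    the diagonal.
    """
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    missing = [s for s in species if s not in taxonomy.index]
    if missing:
        raise ValueError(f"species missing from taxonomy: {missing}")
    levels = ["genus", "family", "order"]
    cum = np.cumsum(step_lengths)
    n = len(species)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = taxonomy.loc[species[i]], taxonomy.loc[species[j]]
            for k, lev in enumerate(levels):
                if a[lev] == b[lev]:
                    d[i, j] = d[j, i] = 2.0 * cum[k]
                    break
            else:
                d[i, j] = d[j, i] = 2.0 * (cum[-1] + step_lengths[-1])
    return pd.DataFrame(d, index=species, columns=species)


def taxonomic_diversity(
    abundances: dict | pd.Series,
    taxonomy: pd.DataFrame | None = None,
    step_lengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Taxonomic diversity Δ: abundance-weighted mean pairwise path length.

    Δ = Σ_{i<j} d_ij x_i x_j / [n(n−1)/2] with n = Σ x_i (Clarke & Warwick).
    Zero for monocultures.  ``abundances`` map species code to abundance —
    counts, or any abundance measure large relative to 1 (the plot pipeline
    passes basal areas in cm², for which the finite-n correction in the
    denominator is negligible and Δ is effectively unit-free).
    """
    ab = pd.Series(abundances, dtype=float)
    ab = ab[ab > 0]
    if ab.empty:
        raise ValueError("empty community")
    if len(ab) == 1:
        return 0.0
    dmat = taxonomic_distance_matrix(list(ab.index), taxonomy, step_lengths)
    x = ab.to_numpy()
    n = x.sum()
    if n <= 1:
        raise ValueError("total abundance must exceed 1 for Δ")
    num = 0.5 * float(x @ dmat.to_numpy() @ x)  # Σ_{i<j} d_ij x_i x_j
    return num / (n * (n - 1.0) / 2.0)


def oak_gall_covariate(
    oak_leaf_records: pd.DataFrame | None, plot_ids
) -> pd.Series:
    """Plot-mean percentage of oak leaves with at least one cynipid gall.

    Tree-level incidences (branch means) are averaged across all sampled
    oaks in each plot; plots without oaks score 0.
    """
    out = pd.Series(0.0, index=pd.Index(plot_ids, name="plot_id"),
                    name="oak_gall_pct")
    if oak_leaf_records is None or oak_leaf_records.empty:
        return out
    per_tree = leaf_gall_incidence(oak_leaf_records)
    tree_plot = oak_leaf_records.drop_duplicates("tree_id").set_index("tree_id")[
        "plot_id"
    ]
    per_plot = per_tree.groupby(tree_plot).mean()
    out.update(per_plot)
    return out


def _community_covariates(trees: pd.DataFrame, taxonomy=None) -> dict:
    ba = basal_area(trees["dbh"])
    by_sp = pd.Series(ba).groupby(trees["species"].to_numpy()).sum()
    shares = by_sp / by_sp.sum()
    return dict(
        richness=int(len(by_sp)),
        shannon=shannon_index(shares.to_numpy()),
        prop_castanea=float(shares.get(HOST_SPECIES, 0.0)),
        tax_div=taxonomic_diversity(by_sp * 1e4, taxonomy),  # m² -> cm²
    )


def plot_covariates(
    trees: pd.DataFrame,
    oak_leaf_records: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Plot-level explanatory variables.

    One row per plot: richness, Shannon H' and chestnut proportion on
    relative basal area, taxonomic diversity Δ, and the oak-gall incidence
    proxy.
    """
    rows = []
    for pid, grp in trees.groupby("plot_id"):
        rows.append(dict(plot_id=pid, **_community_covariates(grp, taxonomy)))
    out = pd.DataFrame(rows).set_index("plot_id")
    out["oak_gall_pct"] = oak_gall_covariate(oak_leaf_records, out.index)
    return out.reset_index()


def neighborhood_covariates(
    neighborhoods: pd.DataFrame,
    trees: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariates over each focal tree's neighbor set (focal tree included).

    ``neighborhoods`` is the output of
    :func:`gallstand.stand_geometry.neighborhood_table`.  Focal trees with
    empty neighbor sets get NaN covariates and are flagged.  Columns are
    prefixed ``nbr_``.
    """
    idx = trees.set_index("tree_id")
    rows = []
    for rec in neighborhoods.itertuples(index=False):
        ids = list(rec.neighbor_ids) + [rec.focal_id]
        if not rec.neighbor_ids:
            rows.append(
                dict(focal_id=rec.focal_id, nbr_richness=np.nan, nbr_shannon=np.nan,
                     nbr_prop_castanea=np.nan, nbr_tax_div=np.nan, undefined=True)
            )
            continue
        cov = _community_covariates(idx.loc[ids].reset_index(), taxonomy)
        rows.append(
            dict(
                focal_id=rec.focal_id,
                nbr_richness=cov["richness"],
                nbr_shannon=cov["shannon"],
                nbr_prop_castanea=cov["prop_castanea"],
                nbr_tax_div=cov["tax_div"],
                undefined=False,
            )
        )
    return pd.DataFrame(rows)
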