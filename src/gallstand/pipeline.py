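"""End-to-end orchestration of the plot- and neighborhood-level analyses.

The two analyses share a damage table (class-resolved crown scores reduced
to total defoliation) and differ in their explanatory variables: the plot
level compares the null model against five univariate models (richness,
Shannon H', chestnut proportion, taxonomic diversity, oak-gall incidence);
the neighborhood level compares fifteen models — the null, the five
plot-level univariates, five neighborhood-scale univariates (including tree
apparency ΔH), and four ΔH multivariate models.  The response throughout is
the natural log of total defoliation in percent; plot identity is the
random intercept.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from gallstand.crown_damage import leaf_gall_incidence, resolve_classes, summarize_damage
from gallstand.diversity import neighborhood_covariates, plot_covariates
from gallstand.inference import ModelSpec, compare_models, pearson, sequential_decomposition
from gallstand.outliers import apply_screen
from gallstand.stand_geometry import neighborhood_table

__all__ = [
    "plot_model_set",
    "neighborhood_model_set",
    "assemble_plot_table",
    "run_plot_level",
    "run_neighborhood_level",
    "run_all",
    "load_dataset",
    "write_dataset",
]

PLOT_PREDICTORS = ("richness", "shannon", "prop_castanea", "tax_div",
                   "oak_gall_pct")
NBR_PREDICTORS = ("nbr_richness", "nbr_shannon", "nbr_prop_castanea",
                  "nbr_tax_div", "delta_h")


def plot_model_set() -> list[ModelSpec]:
    """The six plot-level candidate models: null plus five univariates."""
    specs = [ModelSpec("null", (), "plot")]
    specs += [ModelSpec(p, (p,), "plot") for p in PLOT_PREDICTORS]
    return specs


def neighborhood_model_set() -> list[ModelSpec]:
    """The fifteen neighborhood-level candidates.

    Null; the five plot-level univariates; five neighborhood-scale
    univariates; and four multivariate models pairing ΔH with neighborhood
    richness or taxonomic diversity, additively and with interaction
    (main effects always included).
    """
    specs = [ModelSpec("null", (), "neighborhood")]
    specs += [ModelSpec(f"plot:{p}", (p,), "neighborhood")
              for p in PLOT_PREDICTORS]
    specs += [ModelSpec(p, (p,), "neighborhood") for p in NBR_PREDICTORS]
    for p in ("nbr_richness", "nbr_tax_div"):
        specs.append(ModelSpec(f"{p}+delta_h", (p, "delta_h"), "neighborhood"))
        specs.append(
            ModelSpec(f"{p}*delta_h", (p, "delta_h", f"{p}:delta_h"),
                      "neighborhood")
        )
    return specs


def assemble_plot_table(dataset: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Damage summary for focal trees, merged with plot covariates.

    Adds ``log_td_pct`` (natural log of percent defoliation), the leaf-gall
    incidence where sampled, and the plot-level explanatory variables.
    Fully-dead (excluded) trees are dropped.
    """
    trees = dataset["trees"]
    resolved = resolve_classes(dataset["assessments"])
    leaf_pct = (leaf_gall_incidence(dataset["leaf_records"])
                if len(dataset.get("leaf_records", ())) else None)
    damage = summarize_damage(resolved, leaf_pct)
    damage = damage[~damage["excluded"]].drop(columns="excluded")
    damage = damage.merge(trees[["tree_id", "plot_id"]], on="tree_id")
    covs = plot_covariates(trees, dataset.get("oak_records"))
    out = damage.merge(covs, on="plot_id")
    if (out["td"] <= 0).any():
        raise ValueError("zero defoliation: log response undefined")
    out["log_td_pct"] = np.log(out["td"] * 100.0)
    return out


def run_plot_level(
    dataset: dict[str, pd.DataFrame],
    seed: int = 0,
    keep_outliers: bool = False,
    aicc_on: str = "ml",
) -> dict:
    """Plot-level analysis: damage, covariates, outlier screen, 6-model AICc.

    Also reports the correlation battery: T_D with T_DC and with leaf-gall
    incidence on the full data, and T_D with the never-retained covariates
    on the screened data.
    """
    full = assemble_plot_table(dataset)
    screened, report = apply_screen(full, "td", seed=seed)
    data = full if keep_outliers else screened
    table = compare_models(plot_model_set(), data, "log_td_pct",
                           aicc_on=aicc_on)
    corr = {}
    corr["td_tdc"] = pearson(full["td"], full["tdc"])
    leafy = full.dropna(subset=["leaf_gall_pct"])
    if len(leafy) >= 3:
        corr["td_leaf_gall"] = pearson(leafy["td"], leafy["leaf_gall_pct"])
    for var in ("oak_gall_pct", "tax_div", "prop_castanea"):
        if data[var].std() > 0:
            corr[f"td_{var}"] = pearson(data["td"], data[var])
    return dict(
        data_full=full, data_screened=screened, data_used=data,
        table=table, correlations=corr, outlier_report=report,
        manifest=dict(level="plot", seed=seed, n_assessed=len(full),
                      n_outliers=len(report.flagged_ids),
                      n_analyzed=len(data), mam=table.attrs["mam"]),
    )


def run_neighborhood_level(
    dataset: dict[str, pd.DataFrame],
    seed: int = 0,
    keep_outliers: bool = False,
    aicc_on: str = "ml",
    plot_side: float = 30.0,
    gap: float = 3.0,
) -> dict:
    """Neighborhood-level analysis: margin exclusion, 15-model AICc, and the
    ΔH / Shannon sequential variance decomposition in both orders."""
    full = assemble_plot_table(dataset)
    nbh = neighborhood_table(dataset["trees"], full["tree_id"], plot_side, gap)
    usable = nbh[(~nbh["margin_excluded"]) & (nbh["n_neighbors"] > 0)]
    if usable.empty:
        raise RuntimeError(
            "no focal tree survives margin exclusion; cannot run the "
            "neighborhood analysis"
        )
    ncov = neighborhood_covariates(usable, dataset["trees"])
    merged = (full.merge(usable[["focal_id", "n_neighbors", "delta_h"]],
                         left_on="tree_id", right_on="focal_id")
                  .merge(ncov[~ncov["undefined"]], on="focal_id")
                  .drop(columns=["focal_id", "undefined"]))
    screened, report = apply_screen(merged, "td", seed=seed)
    data = merged if keep_outliers else screened
    table = compare_models(neighborhood_model_set(), data, "log_td_pct",
                           aicc_on=aicc_on)
    seq = sequential_decomposition(data, "log_td_pct", "delta_h", "shannon")
    return dict(
        data_full=merged, data_screened=screened, data_used=data,
        table=table, sequential=seq, outlier_report=report,
        manifest=dict(level="neighborhood", seed=seed,
                      n_focal=len(full), n_non_margin=len(merged),
                      n_outliers=len(report.flagged_ids),
                      n_analyzed=len(data), mam=table.attrs["mam"]),
    )


def run_all(dataset: dict[str, pd.DataFrame], seed: int = 0,
            keep_outliers: bool = False) -> dict:
    """Both analyses on one dataset, sharing the damage table."""
    return dict(
        plot=run_plot_level(dataset, seed=seed, keep_outliers=keep_outliers),
        neighborhood=run_neighborhood_level(dataset, seed=seed,
                                            keep_outliers=keep_outliers),
    )


_TABLES = ("trees", "assessments", "leaf_records", "oak_records")


def write_dataset(dataset: dict[str, pd.DataFrame], outdir) -> None:
    """Write the dataset tables as CSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        if name in dataset:
            dataset[name].to_csv(outdir / f"{name}.csv", index=False)


def load_dataset(indir) -> dict[str, pd.DataFrame]:
    """Read the CSV tables written by :func:`write_dataset` (or field data
    in the same schemas)."""
    indir = Path(indir)
    out = {}
    for name in _TABLES:
        path = indir / f"{name}.csv"
        if path.exists():
            out[name] = pd.read_csv(path)
    if "trees" not in out or "assessments" not in out:
        raise FileNotFoundError(
            f"{indir} must contain at least trees.csv and assessments.csv"
        )
    return out
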