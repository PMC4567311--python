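"""Synthetic stand generator with the statistical structure the analysis assumes.

Emulates the field design: fifteen 30 m × 30 m plots spanning a tree species
richness gradient of 1–4 (plot counts 2, 3, 5, 5), each a mix of Castanea
sativa with Quercus cerris, Q. ilex, Q. petraea and/or Ostrya carpinifolia.
Stems get uniform random positions with a minimum spacing, and sizes drawn
near the observed stand means (chestnut height 15.2 ± 3.3 m, basal area
≈ 0.03 m²).  Focal chestnuts are the largest-DBH chestnuts — six per
monoculture, three per mixed plot.

Damage follows the generative model the analysis is built to recover:

    log T_D(%) = β0 + β_richness · richness + β_ΔH · ΔH + b_plot + ε,

with b_plot ~ N(0, σ_plot²) and ε ~ N(0, σ_resid²).  The latent defoliation
is decomposed into the five crown-condition proportions and discretized into
the seven-class field scale so the scoring pipeline is exercised end to end.
Leaf samples are binomial draws (2 branches × 30 leaves) whose gall
probability increases with the tree's latent defoliation; oak leaves get a
per-plot cynipid-gall incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gallstand.crown_damage import AssessmentClasses
from gallstand.stand_geometry import neighborhood_table

__all__ = [
    "SyntheticConfig",
    "generate_stands",
    "generate_damage",
    "generate_leaf_samples",
    "simulate_dataset",
]

_COMPANIONS = ("QC", "QI", "QP", "OC")


@dataclass
class SyntheticConfig:
    """Study-design and generative parameters for the synthetic stands."""

    plots_per_richness: tuple[int, ...] = (2, 3, 5, 5)
    plot_side: float = 30.0
    trees_per_plot: int = 40
    min_spacing: float = 2.0
    focal_pure: int = 6          # focal chestnuts per monoculture plot
    focal_mixed: int = 3         # per mixed plot
    # size distributions (all species treated alike; Table-level realism only)
    height_mean: float = 15.2    # m
    height_sd: float = 3.3
    dbh_log_mean: float = np.log(19.0)   # cm, lognormal
    dbh_log_sd: float = 0.4
    crown_log_mean: float = np.log(14.0)  # m², lognormal
    crown_log_sd: float = 0.5
    # damage model on log-percent defoliation; beta0 set so mean defoliation
    # lands near the observed 12.7% at the design's richness/apparency mix
    beta0: float = 2.7
    beta_richness: float = -0.26
    beta_delta_h: float = 0.15
    sigma_plot: float = 0.2
    sigma_resid: float = 0.4
    # crown decomposition
    shade_defoliation_ratio: float = 0.8   # P_DS = ratio * P_DL
    side_jitter_sd: float = 0.10           # lognormal sd of per-side re-scoring
    # leaf models
    leaves_per_branch: int = 30
    branches_per_tree: int = 2
    leaf_gall_intercept: float = 0.10      # P(galled leaf) = a + b * T_D + noise
    leaf_gall_slope: float = 0.8
    leaf_gall_noise_sd: float = 0.10       # tree-level scatter around the link
    oak_gall_beta: tuple[float, float] = (2.0, 8.0)  # per-plot incidence ~ Beta
    oaks_sampled_per_plot: int = 3
    neighbor_gap: float = 3.0
    classes: AssessmentClasses = field(default_factory=AssessmentClasses)

    @property
    def n_plots(self) -> int:
        return sum(self.plots_per_richness)


def _positions(rng, n, side, spacing, max_tries=200_000):
    pts = np.empty((0, 2))
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(0, side, size=2)
        if len(pts) == 0 or np.min(np.hypot(*(pts - cand).T)) >= spacing:
            pts = np.vstack([pts, cand])
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place trees at the requested spacing")
    return pts


def generate_stands(config: SyntheticConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate the mapped tree table for all plots.

    Returns one row per tree: ``tree_id, plot_id, richness, species, x, y,
    dbh, height, crown_area, clump_id, is_focal``.  Deterministic given
    ``seed``.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    frames = []
    plot_no = 0
    for richness, n_plots in zip(range(1, len(cfg.plots_per_richness) + 1),
                                 cfg.plots_per_richness):
        for _ in range(n_plots):
            plot_no += 1
            pid = f"P{plot_no:02d}"
            n_focal = cfg.focal_pure if richness == 1 else cfg.focal_mixed
            companions = list(rng.choice(_COMPANIONS, size=richness - 1,
                                         replace=False))
            pool = ["CS"] + companions
            # basal-area-ish composition; keep enough chestnuts for focal picks
            for _ in range(200):
                probs = rng.dirichlet(np.full(len(pool), 3.0))
                species = rng.choice(pool, size=cfg.trees_per_plot, p=probs)
                if ((species == "CS").sum() >= max(n_focal, 2)
                        and len(set(species)) == richness):
                    break
            else:
                raise RuntimeError("could not draw a feasible plot composition")
            xy = _positions(rng, cfg.trees_per_plot, cfg.plot_side,
                            cfg.min_spacing)
            z = rng.normal(size=cfg.trees_per_plot)  # shared size latent
            height = cfg.height_mean + cfg.height_sd * (
                0.6 * z + np.sqrt(1 - 0.36) * rng.normal(size=cfg.trees_per_plot)
            )
            height = np.clip(height, 4.0, None)
            dbh = np.exp(cfg.dbh_log_mean + cfg.dbh_log_sd * (
                0.6 * z + np.sqrt(1 - 0.36) * rng.normal(size=cfg.trees_per_plot)))
            crown = np.exp(cfg.crown_log_mean
                           + cfg.crown_log_sd * rng.normal(size=cfg.trees_per_plot))
            df = pd.DataFrame(
                dict(
                    tree_id=[f"{pid}T{i:02d}" for i in range(cfg.trees_per_plot)],
                    plot_id=pid, richness=richness, species=species,
                    x=xy[:, 0], y=xy[:, 1], dbh=dbh, height=height,
                    crown_area=crown, clump_id=pd.NA,
                )
            )
            chestnuts = df[df["species"] == "CS"].nlargest(n_focal, "dbh")
            df["is_focal"] = df["tree_id"].isin(chestnuts["tree_id"])
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _decompose(td, rng, cfg):
    """Split latent total defoliation into the five crown proportions."""
    pcl = rng.beta(6.0, 4.0)                  # sunlit crown share, mean 0.6
    pdbl = rng.beta(1.0, 11.0)                # dead branches, independent of galls
    pdbs = rng.beta(1.2, 8.0)                 # self-pruning: more loss in shade
    lit = pcl * (1 - pdbl)
    pacl = lit / (lit + (1 - pcl) * (1 - pdbs))
    denom = pacl + cfg.shade_defoliation_ratio * (1 - pacl)
    pdl = min(td / denom, 1.0)
    pds = min(cfg.shade_defoliation_ratio * pdl, 1.0)
    return pcl, pdbl, pdbs, pdl, pds


def generate_damage(
    stands: pd.DataFrame, config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate class-coded crown assessments for the focal trees.

    Returns ``(assessments, latent)``: assessments have one row per focal
    tree × viewing side with the five ``*_class`` codes; latent carries the
    true ``td`` (proportion), its linear-predictor components, and the ΔH
    used by the generator (computed over all mapped trees, margin ignored —
    the generator, unlike the analyst, knows every neighbor).
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    focal = stands[stands["is_focal"]].reset_index(drop=True)
    nbh = neighborhood_table(stands, focal["tree_id"], cfg.plot_side,
                             cfg.neighbor_gap)
    dh = nbh.set_index("focal_id")["delta_h"].fillna(0.0)
    b_plot = {p: rng.normal(0.0, cfg.sigma_plot)
              for p in stands["plot_id"].unique()}
    assess_rows, latent_rows = [], []
    n_clipped = 0
    for rec in focal.itertuples(index=False):
        eta = (cfg.beta0 + cfg.beta_richness * rec.richness
               + cfg.beta_delta_h * dh[rec.tree_id] + b_plot[rec.plot_id]
               + rng.normal(0.0, cfg.sigma_resid))
        td_pct = float(np.exp(eta))
        if td_pct > 95.0:
            n_clipped += 1
        td = np.clip(td_pct, 0.5, 95.0) / 100.0
        pcl, pdbl, pdbs, pdl, pds = _decompose(td, rng, cfg)
        for side in ("A", "B"):
            jitter = np.exp(rng.normal(0.0, cfg.side_jitter_sd, size=5))
            vals = np.clip(np.array([pcl, pdbl, pdbs, pdl, pds]) * jitter, 0, 1)
            assess_rows.append(
                dict(tree_id=rec.tree_id, side=side,
                     pcl_class=cfg.classes.classify(vals[0]),
                     pdbl_class=cfg.classes.classify(vals[1]),
                     pdbs_class=cfg.classes.classify(vals[2]),
                     pdl_class=cfg.classes.classify(vals[3]),
                     pds_class=cfg.classes.classify(vals[4]))
            )
        latent_rows.append(
            dict(tree_id=rec.tree_id, plot_id=rec.plot_id,
                 richness=rec.richness, delta_h_gen=dh[rec.tree_id],
                 td=td, log_td_pct=float(np.log(td * 100.0)))
        )
    if n_clipped > 0.01 * len(focal):
        import warnings
        warnings.warn(
            f"{n_clipped} of {len(focal)} latent defoliation draws exceeded "
            "100%; parameters may be implausible", stacklevel=2,
        )
    return pd.DataFrame(assess_rows), pd.DataFrame(latent_rows)


def generate_leaf_samples(
    stands: pd.DataFrame,
    latent: pd.DataFrame,
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial leaf samples for focal chestnuts and for oaks.

    Chestnut gall probability is ``a + b·T_D`` (clipped to [0, 1]); each
    sampled oak draws at its plot's Beta-distributed cynipid incidence.
    Returns ``(chestnut_records, oak_records)`` with one row per branch:
    ``tree_id, plot_id, branch, n_leaves, n_galled``.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    chest_rows = []
    for rec in latent.itertuples(index=False):
        p = float(np.clip(cfg.leaf_gall_intercept
                          + cfg.leaf_gall_slope * rec.td
                          + rng.normal(0.0, cfg.leaf_gall_noise_sd), 0.0, 1.0))
        for b in range(cfg.branches_per_tree):
            chest_rows.append(
                dict(tree_id=rec.tree_id, plot_id=rec.plot_id, branch=b,
                     n_leaves=cfg.leaves_per_branch,
                     n_galled=int(rng.binomial(cfg.leaves_per_branch, p)))
            )
    oak_rows = []
    oaks = stands[stands["species"].isin(("QC", "QI", "QP"))]
    for pid, grp in oaks.groupby("plot_id"):
        incidence = float(rng.beta(*cfg.oak_gall_beta))
        sampled = grp.nlargest(cfg.oaks_sampled_per_plot, "dbh")
        for tid in sampled["tree_id"]:
            for b in range(cfg.branches_per_tree):
                oak_rows.append(
                    dict(tree_id=tid, plot_id=pid, branch=b,
                         n_leaves=cfg.leaves_per_branch,
                         n_galled=int(rng.binomial(cfg.leaves_per_branch,
                                                   incidence)))
                )
    cols = ["tree_id", "plot_id", "branch", "n_leaves", "n_galled"]
    return (pd.DataFrame(chest_rows, columns=cols),
            pd.DataFrame(oak_rows, columns=cols))


def simulate_dataset(
    config: SyntheticConfig | None = None, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Generate a complete synthetic study: stands, assessments, leaf samples.

    Child seeds for each stage are derived from ``seed`` so the whole dataset
    is reproducible from one integer.
    """
    cfg = config or SyntheticConfig()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    stands = generate_stands(cfg, sub[0])
    assessments, latent = generate_damage(stands, cfg, sub[1])
    leaves, oak_leaves = generate_leaf_samples(stands, latent, cfg, sub[2])
    return dict(trees=stands, assessments=assessments, latent=latent,
                leaf_records=leaves, oak_records=oak_leaves)
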