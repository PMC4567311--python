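"""Neighborhood reconstruction from stand maps.

Trees are mapped as stem coordinates inside square plots; crowns are modelled
as circles whose radius follows from the measured crown projection area
(r = sqrt(area / pi)).  Two trees are neighbors when their crown circles come
within a fixed gap (default 3 m) edge to edge.  Focal trees whose crown plus
gap extends beyond the plot boundary have an unknown neighbor set and are
flagged for exclusion from neighborhood analyses.  Coppice clumps (multiple
stems from one stump) are collapsed to a single tree first.

Apparency ΔH of a focal tree is its height minus the mean height of its
neighbors: positive ΔH means the focal tree stands proud of its neighborhood
and is more visible to a searching herbivore.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "crown_radius",
    "collapse_clumps",
    "find_neighbors",
    "margin_excluded",
    "apparency",
    "neighborhood_table",
]


def crown_radius(crown_area) -> np.ndarray:
    """Radius of the circular crown model, from projected crown area (m²)."""
    area = np.asarray(crown_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("crown areas must be positive")
    return np.sqrt(area / np.pi)


def collapse_clumps(trees: pd.DataFrame) -> pd.DataFrame:
    """Collapse coppice clumps to single trees.

    Rows sharing a non-null ``clump_id`` (within one plot) become one record:
    height is the tallest stem, crown area the sum, basal area the sum of the
    stem basal areas (stored as the equivalent dbh), and the position the
    basal-area-weighted stem centroid.  A clump spanning plots is rejected.
    """
    if "clump_id" not in trees.columns or trees["clump_id"].isna().all():
        return trees.copy()
    singles = trees[trees["clump_id"].isna()].copy()
    out = [singles]
    for cid, grp in trees.dropna(subset=["clump_id"]).groupby("clump_id"):
        if grp["plot_id"].nunique() > 1:
            raise ValueError(f"clump {cid!r} spans multiple plots")
        ba = (grp["dbh"].to_numpy() / 2.0) ** 2  # relative basal areas
        w = ba / ba.sum()
        rec = grp.iloc[0].copy()
        rec["tree_id"] = cid
        rec["x"] = float(np.dot(w, grp["x"]))
        rec["y"] = float(np.dot(w, grp["y"]))
        rec["height"] = float(grp["height"].max())
        rec["crown_area"] = float(grp["crown_area"].sum())
        rec["dbh"] = float(np.sqrt(np.sum(grp["dbh"].to_numpy() ** 2)))
        out.append(rec.to_frame().T)
    collapsed = pd.concat(out, ignore_index=True)
    for col in ("x", "y", "dbh", "height", "crown_area"):
        collapsed[col] = collapsed[col].astype(float)
    return collapsed


def find_neighbors(
    focal_id, trees: pd.DataFrame, gap: float = 3.0
) -> list:
    """IDs of all trees whose crown lies within ``gap`` metres of the focal crown.

    The criterion is edge-to-edge distance between the circular crown models:
    dist(centres) − r_focal − r_other ≤ gap (overlapping crowns included).
    Only trees in the focal tree's plot are considered; the focal tree never
    neighbors itself.  An empty list is a valid result.
    """
    focal = trees.loc[trees["tree_id"] == focal_id]
    if len(focal) != 1:
        raise ValueError(f"focal tree {focal_id!r} not uniquely present")
    focal = focal.iloc[0]
    others = trees[
        (trees["plot_id"] == focal["plot_id"]) & (trees["tree_id"] != focal_id)
    ]
    if others.empty:
        return []
    d = np.hypot(others["x"] - focal["x"], others["y"] - focal["y"])
    edge = d - crown_radius(focal["crown_area"]) - crown_radius(others["crown_area"])
    return others.loc[edge <= gap, "tree_id"].tolist()


def margin_excluded(
    focal: pd.Series, plot_side: float = 30.0, gap: float = 3.0
) -> bool:
    """Whether a focal tree sits too close to the plot edge to trust its neighbor set.

    True when the focal crown circle, buffered by the neighbor gap, extends
    beyond the plot boundary — neighbors outside the plot were never mapped,
    so the neighborhood would be incomplete.
    """
    reach = float(crown_radius(focal["crown_area"])) + gap
    return bool(
        focal["x"] - reach < 0
        or focal["y"] - reach < 0
        or focal["x"] + reach > plot_side
        or focal["y"] + reach > plot_side
    )


def apparency(focal_height: float, neighbor_heights) -> float:
    """Tree apparency ΔH: focal height minus mean neighbor height (m).

    ΔH = (1/N) Σ_i (H_focal − H_neighbor_i).  Undefined without neighbors.
    """
    h = np.asarray(neighbor_heights, dtype=float)
    if h.size == 0:
        raise ValueError("apparency undefined for an empty neighbor set")
    return float(focal_height) - float(h.mean())


def neighborhood_table(
    trees: pd.DataFrame,
    focal_ids,
    plot_side: float = 30.0,
    gap: float = 3.0,
) -> pd.DataFrame:
    """Neighborhood context for each focal tree.

    Clumps are collapsed first.  Returns one row per focal id with columns
    ``focal_id, plot_id, n_neighbors, delta_h, margin_excluded`` and a
    ``neighbor_ids`` list column.  ΔH is NaN for trees without neighbors
    (dropped from neighborhood models with a warning).
    """
    trees = collapse_clumps(trees)
    rows = []
    for fid in focal_ids:
        focal = trees.loc[trees["tree_id"] == fid].iloc[0]
        nbr_ids = find_neighbors(fid, trees, gap=gap)
        nbrs = trees[trees["tree_id"].isin(nbr_ids)]
        if nbr_ids:
            dh = apparency(focal["height"], nbrs["height"])
        else:
            warnings.warn(f"focal tree {fid!r} has no neighbors; ΔH undefined",
                          stacklevel=2)
            dh = np.nan
        rows.append(
            dict(
                focal_id=fid,
                plot_id=focal["plot_id"],
                n_neighbors=len(nbr_ids),
                delta_h=dh,
                margin_excluded=margin_excluded(focal, plot_side, gap),
                neighbor_ids=nbr_ids,
            )
        )
    return pd.DataFrame(rows)
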