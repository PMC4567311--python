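"""Crown-damage scoring from class-coded field assessments.

Field crews score each crown-condition variable on an ordinal percentage
class scale, from one or more viewing sides of the tree.  This module
resolves those class codes to proportions (class midpoints, averaged over
sides), and combines the five assessed proportions into the derived damage
quantities:

* ``T_DBL`` — total dead branches in the sunlit crown part,
* ``P_ACL`` — fraction of the *living* crown that is sunlit,
* ``T_D``   — total defoliation of the living crown (the response variable
  of the damage analysis),
* ``T_DC``  — total damaged crown (defoliation plus sunlit dead branches).

Convention: every crown quantity is a proportion in [0, 1]; percentages
appear only at I/O boundaries.  Leaf-gall incidence, which is conventionally
reported in percent, carries a ``_pct`` suffix and lives in [0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssessmentClasses",
    "DamageSummary",
    "ASSESSMENT_VARIABLES",
    "resolve_classes",
    "total_dead_branches_light",
    "living_crown_light_fraction",
    "total_defoliation",
    "total_damaged_crown",
    "summarize_damage",
    "leaf_gall_incidence",
]

#: The five crown-condition variables scored in the field, in canonical order.
ASSESSMENT_VARIABLES = ("pcl", "pdbl", "pdbs", "pdl", "pds")


@dataclass(frozen=True)
class AssessmentClasses:
    """Ordinal percentage-class scheme for crown-condition scoring.

    The default scheme has seven classes with percent bounds
    0 / 0.5–1 / 1.5–12 / 12.5–25 / 25.5–50 / 50.5–75 / >75; a score is
    resolved to its class midpoint (the top class is taken to span to
    100 %).  Class 0 means "none observed" and resolves to exactly 0.
    """

    lower: tuple[float, ...] = (0.0, 0.5, 1.5, 12.5, 25.5, 50.5, 75.5)
    upper: tuple[float, ...] = (0.0, 1.0, 12.0, 25.0, 50.0, 75.0, 100.0)

    def __post_init__(self) -> None:
        if len(self.lower) != len(self.upper):
            raise ValueError("lower and upper bounds must have equal length")
        mids = self.midpoints_pct
        if not np.all(np.diff(mids) > 0):
            raise ValueError("class midpoints must be strictly increasing")
        if mids[0] != 0.0:
            raise ValueError("class 0 must resolve to 0")

    @property
    def n_classes(self) -> int:
        return len(self.lower)

    @property
    def midpoints_pct(self) -> np.ndarray:
        """Class midpoints in percent (0, 0.75, 6.75, 18.75, 37.75, 62.75, 87.75)."""
        return (np.asarray(self.lower) + np.asarray(self.upper)) / 2.0

    def midpoint(self, class_id: int) -> float:
        """Midpoint of ``class_id`` as a proportion in [0, 1]."""
        cid = int(class_id)
        if cid < 0 or cid >= self.n_classes:
            raise ValueError(f"unknown assessment class code {class_id!r}")
        return float(self.midpoints_pct[cid]) / 100.0

    def classify(self, proportion: float) -> int:
        """Class code whose percent interval contains ``proportion`` (in [0,1])."""
        pct = float(proportion) * 100.0
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"proportion {proportion} outside [0, 1]")
        # assign to the class with the nearest containing interval; values in
        # the gaps between printed bounds (e.g. 1.2%) go to the nearer class
        mids = self.midpoints_pct
        for cid in range(self.n_classes):
            if self.lower[cid] <= pct <= self.upper[cid]:
                return cid
        return int(np.argmin(np.abs(mids - pct)))


@dataclass
class DamageSummary:
    """Derived damage quantities for one focal tree."""

    tree_id: object
    tdbl: float
    pacl: float
    td: float
    tdc: float
    leaf_gall_pct: float | None = None
    excluded: bool = field(default=False)


def _check_unit(name: str, *values: float) -> None:
    for v in values:
        v = float(v)
        if not (0.0 <= v <= 1.0) or not np.isfinite(v):
            raise ValueError(f"{name}: value {v} outside [0, 1]")


def total_dead_branches_light(pcl: float, pdbl: float) -> float:
    """Total dead-branch proportion in the sunlit crown: ``T_DBL = P_CL * P_DBL``."""
    _check_unit("total_dead_branches_light", pcl, pdbl)
    return float(pcl) * float(pdbl)


def living_crown_light_fraction(pcl: float, pdbl: float, pdbs: float) -> float:
    """Fraction of the living crown that is sunlit.

    ``P_ACL = P_CL(1-P_DBL) / [P_CL(1-P_DBL) + (1-P_CL)(1-P_DBS)]``.
    Undefined (ValueError) for a fully dead crown, where the denominator
    vanishes; callers that iterate over trees should catch this and exclude
    the tree (see :func:`summarize_damage`).
    """
    _check_unit("living_crown_light_fraction", pcl, pdbl, pdbs)
    lit = float(pcl) * (1.0 - float(pdbl))
    shade = (1.0 - float(pcl)) * (1.0 - float(pdbs))
    denom = lit + shade
    if denom <= 0.0:
        raise ValueError("fully dead crown: living-crown light fraction undefined")
    return lit / denom


def total_defoliation(pacl: float, pdl: float, pds: float) -> float:
    """Total defoliation of the living crown: ``T_D = P_ACL*P_DL + (1-P_ACL)*P_DS``."""
    _check_unit("total_defoliation", pacl, pdl, pds)
    return float(pacl) * float(pdl) + (1.0 - float(pacl)) * float(pds)


def total_damaged_crown(
    pcl: float, pdbl: float, pdbs: float, pdl: float, pds: float
) -> float:
    """Total damaged crown.

    ``T_DC = P_DL*P_CL(1-P_DBL) + P_DS(1-P_CL)(1-P_DBS) + T_DBL``.  Dead
    branches in the shaded part are deliberately not added: shaded branch
    loss may be self-pruning rather than pest damage.
    """
    _check_unit("total_damaged_crown", pcl, pdbl, pdbs, pdl, pds)
    return (
        float(pdl) * float(pcl) * (1.0 - float(pdbl))
        + float(pds) * (1.0 - float(pcl)) * (1.0 - float(pdbs))
        + total_dead_branches_light(pcl, pdbl)
    )


def resolve_classes(
    assessments: pd.DataFrame, scheme: AssessmentClasses | None = None
) -> pd.DataFrame:
    """Resolve class-coded (or raw-proportion) assessments to one row per tree.

    Parameters
    ----------
    assessments
        One row per tree x viewing side.  Requires ``tree_id`` plus either
        ``<var>_class`` integer codes or ``<var>_prop`` proportions for each
        of ``pcl, pdbl, pdbs, pdl, pds``.
    scheme
        Class scheme; defaults to the seven-class percentage scale.

    Returns
    -------
    DataFrame with columns ``tree_id, pcl, pdbl, pdbs, pdl, pds``, where
    class codes were replaced by class midpoints and, where viewing sides
    disagree, the mean of the per-side midpoints was taken.
    """
    scheme = scheme or AssessmentClasses()
    if "tree_id" not in assessments.columns:
        raise ValueError("assessments must carry a tree_id column")
    out = pd.DataFrame({"tree_id": assessments["tree_id"]})
    for var in ASSESSMENT_VARIABLES:
        ccol, pcol = f"{var}_class", f"{var}_prop"
        if ccol in assessments.columns:
            vals = []
            for tid, code in zip(assessments["tree_id"], assessments[ccol]):
                try:
                    vals.append(scheme.midpoint(code))
                except ValueError as err:
                    raise ValueError(
                        f"tree {tid!r}, variable {var!r}: {err}"
                    ) from None
            out[var] = vals
        elif pcol in assessments.columns:
            vals = assessments[pcol].astype(float)
            if ((vals < 0) | (vals > 1)).any():
                bad = assessments.loc[(vals < 0) | (vals > 1), "tree_id"].iloc[0]
                raise ValueError(
                    f"tree {bad!r}, variable {var!r}: proportion outside [0, 1]"
                )
            out[var] = vals.to_numpy()
        else:
            raise ValueError(f"missing column {ccol!r} or {pcol!r}")
    # average the per-side midpoints per variable, then apply the equations
    return out.groupby("tree_id", sort=False, as_index=False).mean()


def summarize_damage(
    resolved: pd.DataFrame, leaf_pct: pd.Series | None = None
) -> pd.DataFrame:
    """Compute the derived damage quantities for every tree.

    ``resolved`` is the output of :func:`resolve_classes` (one row per tree).
    Trees with a fully dead crown (undefined living-crown light fraction)
    are flagged ``excluded`` with a warning rather than silently zeroed.
    Returns columns ``tree_id, tdbl, pacl, td, tdc, leaf_gall_pct, excluded``.
    """
    rows = []
    for rec in resolved.itertuples(index=False):
        try:
            pacl = living_crown_light_fraction(rec.pcl, rec.pdbl, rec.pdbs)
        except ValueError:
            warnings.warn(
                f"tree {rec.tree_id!r}: fully dead crown, excluded from damage summary",
                stacklevel=2,
            )
            rows.append(
                dict(tree_id=rec.tree_id, tdbl=np.nan, pacl=np.nan, td=np.nan,
                     tdc=np.nan, excluded=True)
            )
            continue
        rows.append(
            dict(
                tree_id=rec.tree_id,
                tdbl=total_dead_branches_light(rec.pcl, rec.pdbl),
                pacl=pacl,
                td=total_defoliation(pacl, rec.pdl, rec.pds),
                tdc=total_damaged_crown(rec.pcl, rec.pdbl, rec.pdbs, rec.pdl, rec.pds),
                excluded=False,
            )
        )
    out = pd.DataFrame(rows)
    if leaf_pct is not None:
        out = out.merge(
            leaf_pct.rename("leaf_gall_pct"), left_on="tree_id", right_index=True,
            how="left",
        )
    else:
        out["leaf_gall_pct"] = np.nan
    return out


def leaf_gall_incidence(leaf_records: pd.DataFrame) -> pd.Series:
    """Per-tree percentage of leaves carrying at least one gall.

    ``leaf_records`` has one row per sampled branch with columns
    ``tree_id, n_leaves, n_galled`` (field protocol: 2 branches x 30 leaves).
    Per-branch percentages are averaged to the tree level.  Branches with
    zero leaves are dropped with a warning.
    """
    req = {"tree_id", "n_leaves", "n_galled"}
    if not req.issubset(leaf_records.columns):
        raise ValueError(f"leaf records need columns {sorted(req)}")
    rec = leaf_records.copy()
    if (rec["n_galled"] > rec["n_leaves"]).any():
        raise ValueError("n_galled exceeds n_leaves on some branch")
    empty = rec["n_leaves"] <= 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} branch(es) with zero leaves dropped", stacklevel=2
        )
        rec = rec[~empty]
    if rec.empty:
        raise ValueError("no branches with leaves")
    rec["branch_pct"] = 100.0 * rec["n_galled"] / rec["n_leaves"]
    return rec.groupby("tree_id")["branch_pct"].mean().rename("leaf_gall_pct")
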