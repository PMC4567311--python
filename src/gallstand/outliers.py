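"""Simulation-based outlier screening for the damage response.

Following the data-exploration protocol of Zuur and colleagues, candidate
outliers in the raw defoliation values are checked by simulating 1,000
Gaussian samples with the size, mean and standard deviation of the observed
data; observations falling outside the 95% envelope of the simulated values
are treated as true outliers.

Two envelope constructions are available.  The default, ``pooled``, takes
the 2.5th and 97.5th percentiles of all pooled simulated values (for n = 70
this expects ~3.5 flags under the null, i.e. a per-point 5% criterion).
``extremes`` instead brackets the simulated per-sample minima and maxima,
which flags only points beyond the plausible range of a whole sample and
expects ~0 flags under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OutlierReport", "screen", "apply_screen"]


@dataclass
class OutlierReport:
    """Result of one simulation screen."""

    n: int
    mean: float
    sd: float
    n_sim: int
    level: float
    envelope: tuple[float, float]
    flagged_ids: list = field(default_factory=list)
    seed: int | None = None
    method: str = "pooled"

    def to_dict(self) -> dict:
        return dict(
            n=self.n, mean=self.mean, sd=self.sd, n_sim=self.n_sim,
            level=self.level, envelope_lower=self.envelope[0],
            envelope_upper=self.envelope[1], flagged_ids=list(self.flagged_ids),
            seed=self.seed, method=self.method,
        )


def screen(
    values,
    ids=None,
    n_sim: int = 1000,
    level: float = 0.95,
    seed: int | None = 0,
    method: str = "pooled",
) -> OutlierReport:
    """Flag values outside the simulated Gaussian envelope.

    Draws ``n_sim`` samples of size ``n`` from N(mean, sd) with mean and sd
    (ddof=1) taken from ``values``, builds the ``level`` envelope, and flags
    raw values outside it.  Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to screen")
    if ids is None:
        ids = np.arange(x.size)
    ids = np.asarray(ids)
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero standard deviation: no outliers flagged", stacklevel=2)
        return OutlierReport(x.size, mean, sd, n_sim, level, (mean, mean),
                             [], seed, method)
    rng = np.random.default_rng(seed)
    sims = rng.normal(mean, sd, size=(n_sim, x.size))
    alpha = 100.0 * (1.0 - level) / 2.0
    if method == "pooled":
        lo, hi = np.percentile(sims, [alpha, 100.0 - alpha])
    elif method == "extremes":
        lo = np.percentile(sims.min(axis=1), alpha)
        hi = np.percentile(sims.max(axis=1), 100.0 - alpha)
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    mask = (x < lo) | (x > hi)
    return OutlierReport(x.size, mean, sd, n_sim, level, (float(lo), float(hi)),
                         list(ids[mask]), seed, method)


def apply_screen(
    data: pd.DataFrame,
    response: str,
    id_column: str = "tree_id",
    n_sim: int = 1000,
    level: float = 0.95,
    seed: int | None = 0,
    method: str = "pooled",
) -> tuple[pd.DataFrame, OutlierReport]:
    """Screen a dataset column and drop flagged rows.

    Returns the filtered dataset and the report; the caller retains the full
    dataset so any analysis can be redone with outliers reincorporated.
    """
    if response not in data.columns:
        raise ValueError(f"response column {response!r} not in dataset")
    report = screen(
        data[response].to_numpy(), ids=data[id_column].to_numpy(),
        n_sim=n_sim, level=level, seed=seed, method=method,
    )
    kept = data[~data[id_column].isin(report.flagged_ids)].reset_index(drop=True)
    return kept, report
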