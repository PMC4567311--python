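"""Linear mixed models, AICc multimodel comparison, and correlation tools.

The damage analysis models log total defoliation tree by tree, with a plot
random intercept absorbing the pseudo-replication of trees within plots.
Candidate fixed structures are compared by AICc; model support is expressed
as Akaike weights, and the minimum adequate model (MAM) is the model with
the fewest estimable parameters among those within 2 AICc units of the best.

Estimation conventions (configurable): slope estimates, standard errors and
t statistics are taken from REML fits; the likelihoods entering AICc are
maximum-likelihood fits, because REML likelihoods are not comparable across
different fixed-effect structures.  t-test p-values use residual degrees of
freedom n − rank(X).  Parameter counts follow the usual mixed-model
bookkeeping: fixed effects + intercept + two variance components, so a null
model has K = 3 and each extra slope adds 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "LmmFit",
    "fit_lmm",
    "aicc",
    "compare_models",
    "select_mam",
    "sequential_decomposition",
    "pearson",
]

_SINGULAR_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a name and its fixed-effect terms.

    Terms are data columns; ``"a:b"`` denotes the product interaction (the
    spec builder is responsible for including main effects alongside any
    interaction).  The empty tuple is the null (intercept-only) model.
    """

    name: str
    terms: tuple[str, ...] = ()
    level: str = "plot"

    @property
    def k(self) -> int:
        """Estimable parameters: slopes + intercept + 2 variance components."""
        return len(self.terms) + 3


@dataclass
class LmmFit:
    """Fitted mixed (or pooled) model, reduced to what the analysis needs."""

    terms: tuple[str, ...]
    method: str                      # 'reml' | 'ml' | 'ols'
    n: int
    params: pd.Series = field(repr=False, default=None)
    bse: pd.Series = field(repr=False, default=None)
    llf: float = np.nan
    scale: float = np.nan
    group_var: float = np.nan
    singular: bool = False
    converged: bool = True

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def pvalues(self, df_resid: int | None = None) -> pd.Series:
        df = df_resid if df_resid is not None else self.n - len(self.params)
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), df), index=self.params.index
        )


def _design(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            X[t] = data[a].to_numpy() * data[b].to_numpy()
        else:
            X[t] = data[t].to_numpy()
    return X


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    terms: tuple[str, ...] = (),
    group: str = "plot_id",
    method: str = "reml",
) -> LmmFit:
    """Fit a random-intercept linear mixed model.

    ``method='reml'`` or ``'ml'`` fits by statsmodels MixedLM; ``'ols'``
    pins the plot variance at zero, which reduces the model to the pooled
    linear model (its ML log-likelihood is reported).  A singular fit
    (plot variance estimated at the zero boundary) is returned flagged,
    not raised.
    """
    y = data[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X = _design(data, terms)
    if method == "ols":
        res = sm.OLS(y, X).fit()
        return LmmFit(terms, "ols", len(y), params=res.params, bse=res.bse,
                      llf=float(res.llf), scale=float(res.scale), group_var=0.0)
    if data[group].nunique() < 2:
        raise ValueError("need at least 2 groups for a mixed model")
    model = sm.MixedLM(y, X, groups=data[group].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=(method == "reml"))
        bse_fe = np.asarray(res.bse_fe)
    gvar = float(np.asarray(res.cov_re)[0, 0])
    # either variance component on the zero boundary makes the fit singular
    # (a quantized response can make within-group values exactly equal,
    # collapsing the residual variance — seen with class-resolved scores)
    total_var = gvar + float(res.scale)
    singular = min(gvar, float(res.scale)) <= _SINGULAR_TOL * total_var
    return LmmFit(
        terms, method, len(y),
        params=pd.Series(np.asarray(res.fe_params), index=X.columns),
        bse=pd.Series(bse_fe, index=X.columns),
        llf=float(res.llf), scale=float(res.scale), group_var=gvar,
        singular=singular, converged=bool(res.converged),
    )


def aicc(llf: float, k: int, n: int) -> float:
    """AICc = −2 logL + 2K + 2K(K+1)/(n−K−1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """Δi and Akaike weights for a vector of AICc scores."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def select_mam(table: pd.DataFrame, threshold: float = 2.0) -> str:
    """Minimum adequate model: lowest K among models with Δi ≤ threshold.

    Ties on K are broken by the lower AICc.
    """
    cand = table[table["delta"] <= threshold]
    cand = cand.sort_values(["K", "aicc"], kind="mergesort")
    return cand.iloc[0]["model"]


def compare_models(
    specs: list[ModelSpec],
    data: pd.DataFrame,
    response: str,
    group: str = "plot_id",
    aicc_on: str = "ml",
    estimates_on: str = "reml",
) -> pd.DataFrame:
    """AICc comparison table across candidate models on a common row set.

    All models are refit on the intersection of rows with complete data for
    every term in any spec, so AICc values are comparable.  Per model the
    table carries K, AICc, Δi, Akaike weight wi, and — for models with at
    least one slope — the estimate ± SE, t and p of the model's first term.
    Failed fits are dropped with a warning and weights renormalized.  The
    table's ``mam`` attribute (``.attrs['mam']``) names the minimum adequate
    model.
    """
    cols = {response, group}
    for s in specs:
        for t in s.terms:
            cols.update(t.split(":"))
    sub = data.dropna(subset=sorted(cols)).reset_index(drop=True)
    n = len(sub)
    rows, fits = [], {}
    for s in specs:
        try:
            f_ll = fit_lmm(sub, response, s.terms, group, method=aicc_on)
            f_est = (f_ll if estimates_on == aicc_on
                     else fit_lmm(sub, response, s.terms, group, method=estimates_on))
        except Exception as err:  # pragma: no cover - defensive
            warnings.warn(f"model {s.name!r} failed to fit: {err}", stacklevel=2)
            continue
        fits[s.name] = f_est
        row = dict(level=s.level, model=s.name, K=s.k,
                   aicc=aicc(f_ll.llf, s.k, n), singular=f_est.singular)
        if s.terms:
            first = s.terms[0]
            row.update(
                estimate=f_est.params[first], se=f_est.bse[first],
                t=f_est.tvalues[first],
                p=f_est.pvalues()[first],
            )
        else:
            row.update(estimate=np.nan, se=np.nan, t=np.nan, p=np.nan)
        rows.append(row)
    if not rows:
        raise RuntimeError("no model could be fitted")
    table = pd.DataFrame(rows)
    table["delta"], table["weight"] = akaike_weights(table["aicc"])
    table = table.sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table = table[["level", "model", "K", "aicc", "delta", "weight",
                   "estimate", "se", "t", "p", "singular"]]
    table.attrs["mam"] = select_mam(table)
    table.attrs["n"] = n
    table.attrs["fits"] = fits
    return table


def sequential_decomposition(
    data: pd.DataFrame,
    response: str,
    pred1: str,
    pred2: str,
    group: str = "plot_id",
) -> pd.DataFrame:
    """Sequential (type-I) variance decomposition for two correlated predictors.

    For each ordering, fits the nested ML sequence null → +first → +both and
    reports the likelihood-ratio p-value of each added term, together with
    the joint-model REML estimate ± SE of each slope.  Separates the unique
    from the shared explanatory contribution of collinear predictors.
    Rejects near-duplicate predictors (|r| > 0.99).
    """
    sub = data.dropna(subset=[response, pred1, pred2, group]).reset_index(drop=True)
    r = np.corrcoef(sub[pred1], sub[pred2])[0, 1]
    if abs(r) > 0.99:
        raise ValueError(f"predictors nearly collinear (r = {r:.3f})")
    joint = fit_lmm(sub, response, (pred1, pred2), group, method="reml")
    rows = []
    for first, second in ((pred1, pred2), (pred2, pred1)):
        ll0 = fit_lmm(sub, response, (), group, method="ml").llf
        ll1 = fit_lmm(sub, response, (first,), group, method="ml").llf
        ll2 = fit_lmm(sub, response, (first, second), group, method="ml").llf
        for term, lr in ((first, 2.0 * (ll1 - ll0)), (second, 2.0 * (ll2 - ll1))):
            rows.append(
                dict(
                    order=f"{first} -> {second}",
                    term=term,
                    lr_chi2=max(lr, 0.0),
                    p=float(stats.chi2.sf(max(lr, 0.0), df=1)),
                    estimate=joint.params[term],
                    se=joint.bse[term],
                )
            )
    out = pd.DataFrame(rows)
    out.attrs["n"] = len(sub)
    out.attrs["correlation"] = float(r)
    return out


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)
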