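"""Mixed-model machinery: AICc, weights, MAM rule, decomposition, Pearson."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gallstand.inference import (
    ModelSpec,
    aicc,
    akaike_weights,
    compare_models,
    fit_lmm,
    pearson,
    select_mam,
    sequential_decomposition,
)


def _grouped_data(seed=0, n_plots=15, per_plot=5, beta_rich=-0.26,
                  sigma_plot=0.2, sigma_resid=0.4):
    rng = np.random.default_rng(seed)
    richness = ([1] * 2 + [2] * 3 + [3] * 5 + [4] * 5)[:n_plots]
    rows = []
    for p, r in enumerate(richness):
        b = rng.normal(0.0, sigma_plot)
        for _ in range(per_plot):
            rows.append(dict(plot_id=f"P{p}", richness=float(r),
                             noise=rng.normal(),
                             y=2.7 + beta_rich * r + b
                               + rng.normal(0.0, sigma_resid)))
    return pd.DataFrame(rows)


class TestAicc:
    def test_formula_arithmetic(self):
        # -2(-69.3) + 2*3 + 2*3*4/62
        assert aicc(-69.3, 3, 66) == pytest.approx(138.6 + 6 + 24 / 62)

    def test_approaches_aic_for_large_n(self):
        assert aicc(-100.0, 4, 10**7) == pytest.approx(208.0, abs=1e-4)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_useless_predictor_raises_aicc_on_average(self):
        diffs = []
        for seed in range(30):
            df = _grouped_data(seed, beta_rich=-0.26)
            n = len(df)
            base = aicc(fit_lmm(df, "y", ("richness",), method="ml").llf, 4, n)
            more = aicc(fit_lmm(df, "y", ("richness", "noise"),
                                method="ml").llf, 5, n)
            diffs.append(more - base)
        assert np.mean(diffs) > 0


class TestWeightsAndMam:
    def test_delta_two_weights(self):
        delta, w = akaike_weights([100.0, 102.0])
        assert list(delta) == [0.0, 2.0]
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=5e-4)
        assert w[1] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)), abs=5e-4)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            _, w = akaike_weights(rng.uniform(50, 150, size=8))
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert (w >= 0).all()

    def test_identical_models_split_weight(self):
        df = _grouped_data(1)
        specs = [ModelSpec("m1", ("richness",)), ModelSpec("m2", ("richness",))]
        table = compare_models(specs, df, "y")
        assert table["delta"].max() == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(table["weight"], 0.5, atol=1e-6)

    def test_mam_prefers_fewer_parameters_within_two_units(self):
        table = pd.DataFrame(
            dict(model=["null", "a", "b"], K=[3, 4, 4],
                 aicc=[101.9, 100.0, 100.14])
        )
        table["delta"] = table["aicc"] - table["aicc"].min()
        assert select_mam(table) == "null"

    def test_mam_matches_brute_force(self):
        """The selection rule agrees with exhaustive enumeration on random tables."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            k = rng.integers(3, 7, size=6)
            a = rng.uniform(100, 110, size=6)
            table = pd.DataFrame(dict(model=[f"m{i}" for i in range(6)],
                                      K=k, aicc=a, delta=a - a.min()))
            best = min(
                (row for row in table.itertuples() if row.delta <= 2.0),
                key=lambda r: (r.K, r.aicc),
            )
            assert select_mam(table) == best.model

    def test_mam_stable_under_aicc_shift(self):
        rng = np.random.default_rng(5)
        k = rng.integers(3, 7, size=6)
        a = rng.uniform(100, 110, size=6)
        t1 = pd.DataFrame(dict(model=list("abcdef"), K=k, aicc=a,
                               delta=a - a.min()))
        a2 = a + 500.0
        t2 = pd.DataFrame(dict(model=list("abcdef"), K=k, aicc=a2,
                               delta=a2 - a2.min()))
        assert select_mam(t1) == select_mam(t2)


class TestFitLmm:
    def test_intercept_only_recovers_grand_mean(self):
        df = _grouped_data(2, sigma_plot=0.0)
        fit = fit_lmm(df, "y", ())
        assert fit.params["Intercept"] == pytest.approx(df["y"].mean(), abs=1e-4)

    def test_slope_recovery_within_two_se(self):
        df = _grouped_data(3)
        fit = fit_lmm(df, "y", ("richness",))
        assert abs(fit.params["richness"] + 0.26) < 2 * fit.bse["richness"]

    def test_ols_oracle_normal_equations(self):
        """The zero-plot-variance path reproduces hand-computed least squares."""
        df = _grouped_data(4)
        fit = fit_lmm(df, "y", ("richness",), method="ols")
        X = np.column_stack([np.ones(len(df)), df["richness"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"])
        resid = df["y"] - X @ beta
        s2 = (resid @ resid) / (len(df) - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert fit.params.to_numpy() == pytest.approx(beta, rel=1e-10)
        assert fit.bse.to_numpy() == pytest.approx(se, rel=1e-10)

    def test_mixed_fit_approaches_ols_without_plot_variance(self):
        df = _grouped_data(6, n_plots=15, per_plot=20, sigma_plot=0.0)
        mixed = fit_lmm(df, "y", ("richness",), method="ml")
        ols = fit_lmm(df, "y", ("richness",), method="ols")
        assert mixed.params["richness"] == pytest.approx(
            ols.params["richness"], abs=0.02)
        assert mixed.singular or mixed.group_var < 0.05 * mixed.scale

    def test_nonfinite_response_rejected(self):
        df = _grouped_data(7)
        df.loc[0, "y"] = np.nan
        with pytest.raises(ValueError):
            fit_lmm(df, "y", ("richness",))

    def test_scale_invariance_of_log_response(self):
        """Multiplying defoliation by any constant shifts log by a constant:
        slopes, t statistics, Δi and weights are unchanged."""
        df = _grouped_data(8)
        specs = [ModelSpec("null", ()), ModelSpec("rich", ("richness",))]
        t1 = compare_models(specs, df, "y")
        df2 = df.assign(y=df["y"] + np.log(100.0))
        t2 = compare_models(specs, df2, "y")
        for col in ("delta", "weight", "estimate", "se", "t"):
            assert t1[col].fillna(0).to_numpy() == pytest.approx(
                t2[col].fillna(0).to_numpy(), abs=1e-5)


class TestCompareModels:
    def test_common_row_set_enforced(self):
        df = _grouped_data(9)
        df.loc[:4, "noise"] = np.nan
        specs = [ModelSpec("null", ()), ModelSpec("n", ("noise",))]
        table = compare_models(specs, df, "y")
        assert table.attrs["n"] == len(df) - 5

    def test_k_bookkeeping(self):
        df = _grouped_data(10)
        df["inter"] = df["richness"] * df["noise"]
        specs = [
            ModelSpec("null", ()),
            ModelSpec("uni", ("richness",)),
            ModelSpec("bi", ("richness", "noise")),
            ModelSpec("int", ("richness", "noise", "richness:noise")),
        ]
        table = compare_models(specs, df, "y").set_index("model")
        assert table.loc["null", "K"] == 3
        assert table.loc["uni", "K"] == 4
        assert table.loc["bi", "K"] == 5
        assert table.loc["int", "K"] == 6


class TestSequentialDecomposition:
    def test_orthogonal_predictors_order_free(self):
        rng = np.random.default_rng(11)
        n = 200
        df = pd.DataFrame(dict(
            plot_id=np.repeat(np.arange(10), 20),
            a=rng.normal(size=n), b=rng.normal(size=n)))
        df["y"] = 0.5 * df["a"] - 0.5 * df["b"] + rng.normal(0, 1, n)
        out = sequential_decomposition(df, "y", "a", "b")
        by = out.set_index(["order", "term"])
        assert by.loc[("a -> b", "a"), "p"] == pytest.approx(
            by.loc[("b -> a", "a"), "p"], abs=0.05)
        assert by.loc[("a -> b", "b"), "p"] == pytest.approx(
            by.loc[("b -> a", "b"), "p"], abs=0.05)

    def test_duplicate_predictor_rejected(self):
        df = _grouped_data(12)
        df["copy"] = df["richness"]
        with pytest.raises(ValueError, match="collinear"):
            sequential_decomposition(df, "y", "richness", "copy")

    def test_causal_predictor_survives_both_orders(self):
        """With only apparency causal and diversity correlated r ≈ -0.5,
        apparency stays significant in both orders; diversity only when
        fitted first."""
        rng = np.random.default_rng(13)
        rows = []
        for p in range(15):
            b = rng.normal(0, 0.1)
            for _ in range(5):
                dh = rng.normal(0, 2)
                sh = -0.25 * dh + rng.normal(0, 0.87)  # r ~ -0.5
                rows.append(dict(plot_id=p, delta_h=dh, shannon=sh,
                                 y=2.0 + 0.15 * dh + b + rng.normal(0, 0.3)))
        df = pd.DataFrame(rows)
        out = sequential_decomposition(df, "y", "delta_h", "shannon")
        by = out.set_index(["order", "term"])
        assert by.loc[("delta_h -> shannon", "delta_h"), "p"] < 0.01
        assert by.loc[("shannon -> delta_h", "delta_h"), "p"] < 0.01
        assert by.loc[("shannon -> delta_h", "shannon"), "p"] < 0.05
        assert by.loc[("delta_h -> shannon", "shannon"), "p"] > 0.05
        # joint-model estimates identical regardless of order
        ests = out.groupby("term")["estimate"].nunique()
        assert (ests == 1).all()


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
         ([1, 2, 3, 4], [8, 6, 4, 2], -1.0),
         ([1, 2, 3, 4], [2, 1, 4, 3], 0.6)],
    )
    def test_examples(self, x, y, expected):
        r, p, n = pearson(x, y)
        assert r == pytest.approx(expected)
        assert n == 4

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_nan_pairs_dropped(self):
        r, p, n = pearson([1, 2, 3, np.nan], [2, 4, 6, 8])
        assert n == 3
        assert r == pytest.approx(1.0)
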