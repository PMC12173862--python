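"""Tests for OLS with cluster-robust SEs, heterogeneity splits, SUR and LASSO."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ruraldiet import (
    RegressionSpec,
    SubgroupScheme,
    fit_lasso_cv,
    fit_main_model,
    fit_sur,
    run_heterogeneity,
)
from ruraldiet.inference import significance_stars


def sandwich_oracle(y, X, groups):
    """Independently coded cluster sandwich:
    c * (X'X)^-1 (sum_g X_g'u_g u_g'X_g) (X'X)^-1,
    c = G/(G-1) * (n-1)/(n-k)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    u = y - X @ beta
    meat = np.zeros((k, k))
    labels = pd.unique(groups)
    G = len(labels)
    for g in labels:
        Xg = X[groups == g]
        ug = u[groups == g]
        s = Xg.T @ ug
        meat += np.outer(s, s)
    bread = np.linalg.inv(X.T @ X)
    c = G / (G - 1) * (n - 1) / (n - k)
    return beta, np.sqrt(np.diag(c * bread @ meat @ bread))


def small_dataset(n=20, seed=0, n_counties=2):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "household_id": [f"H{i}" for i in range(n)],
            "county_id": rng.choice([f"C{j}" for j in range(n_counties)], n),
            "village_id": [f"V{i % 4}" for i in range(n)],
            "ratio_under18": rng.uniform(0, 50, n),
            "ratio_over65": rng.uniform(0, 80, n),
            "income": rng.lognormal(0.5, 0.8, n),
            "dki": rng.integers(0, 10, n).astype(float),
        }
    )
    df["EI"] = 1.0 - 0.002 * df["ratio_over65"] + 0.02 * df["income"] + rng.normal(0, 0.2, n)
    return df


SMALL_SPEC = RegressionSpec(outcome="EI", controls=("dki",))


class TestMainModel:
    def test_singleton_cluster_se_matches_hand_coded_sandwich(self):
        """Household-level clustering with one row per household equals the
        independently coded HC1 sandwich to 1e-10 relative error."""
        df = small_dataset()
        fit = fit_main_model(df, SMALL_SPEC)
        from ruraldiet.inference import build_design

        y, X, groups, _ = build_design(df, SMALL_SPEC)
        beta, se = sandwich_oracle(y.to_numpy(), X.to_numpy(), groups.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-10)
        np.testing.assert_allclose(fit.se.to_numpy(), se, rtol=1e-10)

    def test_true_cluster_se_matches_hand_coded_sandwich(self):
        df = small_dataset(n=60, seed=2, n_counties=3)
        spec = RegressionSpec(outcome="EI", controls=("dki",), cluster="village_id")
        fit = fit_main_model(df, spec)
        from ruraldiet.inference import build_design

        y, X, groups, _ = build_design(df, spec)
        beta, se = sandwich_oracle(y.to_numpy(), X.to_numpy(), groups.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-8)
        np.testing.assert_allclose(fit.se.to_numpy(), se, rtol=1e-8)

    def test_county_constant_column_absorbed_by_fixed_effects(self):
        """A regressor constant within county changes nothing once county
        dummies are present (it is dropped as collinear)."""
        df = small_dataset(n=40, seed=3)
        base = fit_main_model(df, SMALL_SPEC)
        df2 = df.copy()
        df2["county_flag"] = (df2["county_id"] == "C1").astype(float)
        spec2 = RegressionSpec(
            outcome="EI", controls=("dki", "county_flag"), on_collinear="drop"
        )
        fit2 = fit_main_model(df2, spec2)
        for term in ("ratio_under18", "ratio_over65", "income", "dki"):
            assert fit2.params[term] == pytest.approx(base.params[term], rel=1e-9)

    def test_duplicated_column_raises_collinearity_error(self):
        df = small_dataset(n=40)
        df["income_copy"] = df["income"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_main_model(
                df, RegressionSpec(outcome="EI", controls=("dki", "income_copy"))
            )

    def test_listwise_deletion_counts_dropped_rows(self):
        df = small_dataset(n=30)
        df.loc[3, "income"] = np.nan
        df.loc[7, "EI"] = np.nan
        fit = fit_main_model(df, SMALL_SPEC)
        assert fit.n == 28 and fit.n_dropped == 2

    def test_too_few_rows_rejected(self):
        df = small_dataset(n=6)
        with pytest.raises(ValueError, match="parameters"):
            fit_main_model(df, SMALL_SPEC)

    def test_stars_convention(self):
        assert significance_stars(0.005) == "***"
        assert significance_stars(0.03) == "**"
        assert significance_stars(0.07) == "*"
        assert significance_stars(0.2) == ""

    def test_planted_sign_recovery_single_dataset(self, default_scored):
        fit = fit_main_model(default_scored, RegressionSpec(outcome="EI"))
        assert fit.params["ratio_over65"] < 0
        assert fit.params["income"] > 0
        assert fit.pvalues["income"] < 0.05
        assert fit.n == 1080


class TestHeterogeneity:
    def test_median_split_halves_sample(self):
        df = small_dataset(n=100, seed=5)
        fits = run_heterogeneity(
            df, SMALL_SPEC, SubgroupScheme(variable="income", rule="median", min_n=10)
        )
        assert [f.n for f in fits.values()] == [50, 50]
        assert list(fits) == ["low", "high"]

    def test_custom_thresholds_reproduce_configured_cuts(self, default_scored):
        inc = default_scored["income"]
        # unequal three-way split akin to a 575/310/194 partition of 1079
        cuts = (inc.quantile(575 / 1079), inc.quantile(885 / 1079))
        fits = run_heterogeneity(
            default_scored,
            RegressionSpec(outcome="EI"),
            SubgroupScheme(variable="income", rule="custom", thresholds=cuts,
                           labels=("low", "middle", "high")),
        )
        ns = [f.n for f in fits.values()]
        assert sum(ns) == 1080
        assert ns[0] > ns[1] > ns[2]

    def test_income_excluded_from_its_own_tercile_split(self, default_scored):
        fits = run_heterogeneity(
            default_scored,
            RegressionSpec(outcome="EI"),
            SubgroupScheme(variable="income", rule="tercile"),
        )
        for f in fits.values():
            assert "income" not in f.params.index
        # override keeps it
        fits2 = run_heterogeneity(
            default_scored,
            RegressionSpec(outcome="EI"),
            SubgroupScheme(variable="income", rule="tercile", include_split_var=True),
        )
        for f in fits2.values():
            assert "income" in f.params.index

    def test_other_split_keeps_income(self, default_scored):
        fits = run_heterogeneity(
            default_scored,
            RegressionSpec(outcome="EI"),
            SubgroupScheme(variable="land_ha", rule="median"),
        )
        for f in fits.values():
            assert "income" in f.params.index

    def test_planted_interaction_recovered_in_strata(self):
        """An elderly effect present only below the income median shows up in
        the low stratum and not the high one."""
        rng = np.random.default_rng(9)
        n = 2000
        df = pd.DataFrame(
            {
                "household_id": [f"H{i}" for i in range(n)],
                "county_id": rng.choice(["C1", "C2"], n),
                "ratio_under18": rng.uniform(0, 50, n),
                "ratio_over65": rng.uniform(0, 80, n),
                "income": rng.lognormal(0.5, 0.8, n),
                "dki": rng.integers(0, 10, n).astype(float),
            }
        )
        low = df["income"] < df["income"].median()
        df["EI"] = 1.0 + np.where(low, -0.004, 0.0) * df["ratio_over65"] + rng.normal(0, 0.15, n)
        fits = run_heterogeneity(
            df, SMALL_SPEC, SubgroupScheme(variable="income", rule="median")
        )
        assert fits["low"].params["ratio_over65"] == pytest.approx(-0.004, abs=3 * fits["low"].se["ratio_over65"])
        assert fits["low"].pvalues["ratio_over65"] < 0.01
        assert fits["high"].pvalues["ratio_over65"] > 0.05

    def test_small_stratum_rejected(self):
        df = small_dataset(n=40)
        with pytest.raises(ValueError, match="min_n"):
            run_heterogeneity(
                df, SMALL_SPEC, SubgroupScheme(variable="income", rule="median", min_n=30)
            )


def sur_dataset(n=150, G=4, seed=0, correlated=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "household_id": [f"H{i}" for i in range(n)],
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(0, 1, n),
        }
    )
    if correlated:
        L = np.array([[1.0, 0, 0, 0], [0.6, 0.8, 0, 0], [0.3, 0.3, 0.9, 0], [0.2, 0.2, 0.2, 0.95]])
        E = rng.normal(0, 1, (n, G)) @ L.T[:G, :G]
    else:
        E = rng.normal(0, 1, (n, G))
    for g in range(G):
        df[f"y{g}"] = 0.5 * df["x1"] + (0.2 * g) * df["x2"] + E[:, g]
    return df


SUR_SPEC = RegressionSpec(outcome="y0", focal=("x1", "x2"), controls=(),
                          fixed_effect=None, cluster=None)


class TestSur:
    def test_identical_regressors_reduce_to_per_equation_ols(self):
        """With the same X in every equation, feasible GLS equals OLS
        (textbook equivalence), checked against statsmodels."""
        df = sur_dataset()
        outs = ["y0", "y1", "y2", "y3"]
        system = fit_sur(df, outs, SUR_SPEC)
        X = sm.add_constant(df[["x1", "x2"]].to_numpy())
        for j, out in enumerate(outs):
            ols = sm.OLS(df[out].to_numpy(), X).fit()
            np.testing.assert_allclose(
                system.params[out].to_numpy(), ols.params, rtol=1e-8
            )

    def test_wald_invariant_to_equation_ordering(self):
        df = sur_dataset()
        a = fit_sur(df, ["y0", "y1", "y2", "y3"], SUR_SPEC)
        b = fit_sur(df, ["y3", "y1", "y0", "y2"], SUR_SPEC)
        sa, dfa, _ = a.wald_joint("x1")
        sb, dfb, _ = b.wald_joint("x1")
        assert dfa == dfb == 4
        assert sa == pytest.approx(sb, rel=1e-8)

    def test_sigma_symmetric_psd(self):
        system = fit_sur(sur_dataset(), ["y0", "y1", "y2", "y3"], SUR_SPEC)
        S = system.sigma.to_numpy()
        np.testing.assert_allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_mismatched_rows_rejected(self):
        df = sur_dataset()
        df.loc[0, "y1"] = np.nan
        with pytest.raises(ValueError, match="different rows"):
            fit_sur(df, ["y0", "y1"], SUR_SPEC)

    def test_singular_covariance_falls_back_to_ols(self, caplog):
        df = sur_dataset(correlated=False)
        df["y1"] = df["y0"]  # perfectly dependent equations -> singular sigma
        import logging

        with caplog.at_level(logging.WARNING):
            system = fit_sur(df, ["y0", "y1"], SUR_SPEC)
        assert not system.fgls
        np.testing.assert_allclose(
            system.params["y0"].to_numpy(), system.params["y1"].to_numpy()
        )

    def test_unknown_wald_term_rejected(self):
        system = fit_sur(sur_dataset(), ["y0", "y1"], SUR_SPEC)
        with pytest.raises(ValueError):
            system.wald_joint("nope")


class TestLasso:
    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(3)
        n = 80
        df = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("abcd"))
        df["y"] = 1.0 + 2 * df["a"] - df["b"] + rng.normal(0, 0.5, n)
        fit = fit_lasso_cv(df, "y", ["a", "b", "c", "d"], folds=5, seed=0,
                           lambda_min_ratio=1e-12)
        Xc = (df[list("abcd")] - df[list("abcd")].mean()) / df[list("abcd")].std(ddof=0)
        yc = df["y"] - df["y"].mean()
        ols = np.linalg.lstsq(Xc.to_numpy(), yc.to_numpy(), rcond=None)[0]
        from ruraldiet.inference import _lasso_at

        np.testing.assert_allclose(
            _lasso_at(Xc.to_numpy(), yc.to_numpy(), 0.0), ols, rtol=1e-8
        )

    def test_penalty_above_lambda_max_zeroes_all_slopes(self):
        rng = np.random.default_rng(4)
        n = 60
        df = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        df["y"] = df["a"] + rng.normal(0, 1, n)
        fit = fit_lasso_cv(df, "y", ["a", "b", "c"], folds=5, seed=1)
        # the first grid point is lambda_max: every slope already zero there
        assert np.allclose(fit.coef_path[:, 0], 0.0)

    def test_orthonormal_predictor_matches_soft_threshold_closed_form(self):
        """For a single unit-norm predictor the Eq. penalised solution is
        beta = sign(b) * max(|b| - lambda/2, 0) with b = x'y."""
        rng = np.random.default_rng(5)
        n = 50
        x = rng.normal(0, 1, n)
        x -= x.mean()
        x /= np.linalg.norm(x)  # orthonormal: x'x = 1
        y = 3.0 * x + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"x": x, "y": y})
        from ruraldiet.inference import _lasso_at

        b = float(x @ (y - y.mean()))
        for lam in [0.1, 0.5, 1.0, 2 * abs(b), 4 * abs(b)]:
            got = _lasso_at(x[:, None], y - y.mean(), lam)[0]
            want = np.sign(b) * max(abs(b) - lam / 2, 0.0)
            assert got == pytest.approx(want, abs=1e-8)

    def test_orthonormal_path_monotone_entry(self):
        """In an orthonormal design coefficients enter monotonically as the
        penalty decreases (piecewise-linear soft-threshold path)."""
        rng = np.random.default_rng(6)
        n, p = 60, 5
        Q, _ = np.linalg.qr(rng.normal(0, 1, (n, p)))
        Q -= Q.mean(axis=0)
        y = Q @ np.array([3.0, -2.0, 1.0, 0.5, 0.0]) + rng.normal(0, 0.2, n)
        df = pd.DataFrame(Q, columns=[f"x{j}" for j in range(p)])
        df["y"] = y
        fit = fit_lasso_cv(df, "y", list(df.columns[:-1]), folds=5, seed=2,
                           standardize=False, n_lambda=50)
        abs_path = np.abs(fit.coef_path)
        diffs = np.diff(abs_path, axis=1)  # lambdas decrease along the path
        assert (diffs >= -1e-8).all()

    def test_cv_folds_partition_sample(self):
        df = sur_dataset(n=95)
        fit = fit_lasso_cv(df, "y0", ["x1", "x2"], folds=10, seed=3)
        counts = np.bincount(fit.fold_assignment, minlength=10)
        assert counts.sum() == 95 and counts.min() >= 9

    def test_selection_keeps_true_predictors(self):
        """Income and elderly share, the only true predictors among noise
        columns, survive CV-selected LASSO in >= 90% of replicates."""
        kept = 0
        reps = 50
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            n = 200
            df = pd.DataFrame(
                {
                    "income": rng.lognormal(0.5, 0.8, n),
                    "ratio_over65": rng.uniform(0, 80, n),
                    **{f"z{j}": rng.normal(0, 1, n) for j in range(6)},
                }
            )
            df["EI"] = 0.03 * df["income"] - 0.004 * df["ratio_over65"] + rng.normal(0, 0.2, n)
            fit = fit_lasso_cv(df, "EI", list(df.columns[:-1]), folds=10,
                               seed=s, n_lambda=60)
            if {"income", "ratio_over65"} <= set(fit.selected):
                kept += 1
        assert kept / reps >= 0.9

    def test_too_few_rows_for_folds_rejected(self):
        df = sur_dataset(n=8)
        with pytest.raises(ValueError, match="folds"):
            fit_lasso_cv(df, "y0", ["x1"], folds=10)
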