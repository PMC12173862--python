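"""Regression inference for the dietary-health analysis.

Four estimators:

* the main multivariate linear model ``y_i = a + sum_j b_j ratio_j +
  g * income_i + theta' Z_i + e_i`` with county fixed effects, estimated by
  OLS with cluster-robust (sandwich) standard errors — with one observation
  per household, clustering at the household level coincides with the
  HC1 heteroskedasticity-robust estimator, so the cluster factor is
  configurable (household / village / county);
* subgroup re-fits for heterogeneity analysis (tercile / median / custom
  splits);
* an eight-equation seemingly-unrelated-regressions system for food-group
  quantities, estimated by one-step feasible GLS, with chi-square joint
  Wald tests of a regressor across all equations;
* an L1-penalised (LASSO) robustness check, parameterised directly in the
  objective ``sum_i (y_i - x_i'b)^2 + lambda * sum_j |b_j|`` with the
  penalty chosen by 10-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso, lasso_path

from .survey import DERIVED_REGRESSORS, derive_regressors

logger = logging.getLogger(__name__)

DEFAULT_FOCAL = ("ratio_under18", "ratio_over65", "income")
DEFAULT_CONTROLS = DERIVED_REGRESSORS


def significance_stars(p: float) -> str:
    """Conventional three-tier stars: * p<0.1, ** p<0.05, *** p<0.01."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress on what; the 18-65 ratio is the omitted reference."""

    outcome: str = "EI"
    focal: tuple[str, ...] = DEFAULT_FOCAL
    controls: tuple[str, ...] = DEFAULT_CONTROLS
    fixed_effect: str | None = "county_id"
    cluster: str | None = "household_id"
    on_collinear: str = "error"  # "error" | "drop"

    def __post_init__(self) -> None:
        terms = list(self.focal) + list(self.controls)
        if len(terms) != len(set(terms)):
            raise ValueError("duplicated regressor in focal/controls")
        if "ratio_18_65" in terms:
            raise ValueError("ratio_18_65 is the omitted reference category")
        if self.on_collinear not in ("error", "drop"):
            raise ValueError("on_collinear must be 'error' or 'drop'")


@dataclass
class RegressionFit:
    """Point estimates with cluster-robust inference for one model."""

    outcome: str
    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n: int
    n_dropped: int
    fixed_effect: str | None
    cluster: str | None
    stratum: str | None = None
    cov: pd.DataFrame | None = None

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.se, "upper": self.params + z * self.se}
        )

    def table(self) -> pd.DataFrame:
        """Tidy coefficient table (term, estimate, se, t, p, stars)."""
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "se": self.se.values,
                "t": self.tvalues.values,
                "p": self.pvalues.values,
                "stars": [significance_stars(p) for p in self.pvalues],
                "model": self.outcome,
                "stratum": self.stratum or "",
            }
        )


def _prepare(data: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    need_ln = any(
        c.startswith("ln_") and c not in data.columns
        for c in (*spec.focal, *spec.controls)
    )
    return derive_regressors(data) if need_ln else data


def build_design(
    data: pd.DataFrame, spec: RegressionSpec
) -> tuple[pd.Series, pd.DataFrame, pd.Series | None, int]:
    """Assemble (y, X, cluster groups, n_dropped) with listwise deletion.

    X includes an intercept and, when a fixed-effect factor is set, its
    dummy columns (first level omitted).
    """
    data = _prepare(data, spec)
    cols = [spec.outcome, *spec.focal, *spec.controls]
    if spec.fixed_effect:
        cols.append(spec.fixed_effect)
    if spec.cluster:
        cols.append(spec.cluster)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not found in data: {missing}")
    sub = data[list(dict.fromkeys(cols))]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info("listwise deletion dropped %d incomplete rows", n_dropped)

    X = complete[list(spec.focal) + list(spec.controls)].astype(float)
    X.insert(0, "const", 1.0)
    if spec.fixed_effect:
        dummies = pd.get_dummies(
            complete[spec.fixed_effect], prefix=spec.fixed_effect,
            drop_first=True, dtype=float,
        )
        X = pd.concat([X, dummies], axis=1)
    y = complete[spec.outcome].astype(float)
    groups = complete[spec.cluster] if spec.cluster else None
    return y, X, groups, n_dropped


def _resolve_collinearity(X: pd.DataFrame, how: str) -> pd.DataFrame:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank == X.shape[1]:
        return X
    if how == "error":
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "set on_collinear='drop' to drop dependent columns"
        )
    # greedy left-to-right selection: earlier columns (intercept, focal
    # regressors) take precedence over later controls and dummies
    keep: list[int] = []
    current = np.empty((A.shape[0], 0))
    for i in range(A.shape[1]):
        cand = np.column_stack([current, A[:, i]])
        if np.linalg.matrix_rank(cand) > current.shape[1]:
            keep.append(i)
            current = cand
    dropped = [c for i, c in enumerate(X.columns) if i not in keep]
    logger.warning("dropping collinear columns: %s", dropped)
    return X.iloc[:, keep]


def fit_main_model(data: pd.DataFrame, spec: RegressionSpec) -> RegressionFit:
    """OLS with county fixed effects and cluster-robust standard errors."""
    y, X, groups, n_dropped = build_design(data, spec)
    if len(y) <= X.shape[1]:
        raise ValueError(f"n = {len(y)} rows <= {X.shape[1]} parameters")
    X = _resolve_collinearity(X, spec.on_collinear)
    if groups is not None and groups.nunique() < 2:
        raise ValueError("cluster factor has fewer than 2 groups")
    model = sm.OLS(y.to_numpy(), X.to_numpy())
    if groups is not None:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups.to_numpy()})
    else:
        res = model.fit(cov_type="HC1")
    idx = X.columns
    return RegressionFit(
        outcome=spec.outcome,
        params=pd.Series(res.params, index=idx),
        se=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        n=int(res.nobs),
        n_dropped=n_dropped,
        fixed_effect=spec.fixed_effect,
        cluster=spec.cluster,
        cov=pd.DataFrame(res.cov_params(), index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# heterogeneity


@dataclass(frozen=True)
class SubgroupScheme:
    """How to split the sample for a heterogeneity analysis."""

    variable: str
    rule: str = "median"  # "tercile" | "median" | "custom"
    thresholds: tuple[float, ...] = ()
    labels: tuple[str, ...] | None = None
    min_n: int = 30
    include_split_var: bool | None = None  # None = contract default

    def __post_init__(self) -> None:
        if self.rule not in ("tercile", "median", "custom"):
            raise ValueError(f"unknown cut rule {self.rule!r}")
        if self.rule == "custom" and not self.thresholds:
            raise ValueError("custom rule needs thresholds")


def _strata(values: pd.Series, scheme: SubgroupScheme) -> pd.Series:
    if scheme.rule == "median":
        cuts = [values.quantile(0.5)]
        default_labels = ["low", "high"]
    elif scheme.rule == "tercile":
        cuts = [values.quantile(1 / 3), values.quantile(2 / 3)]
        default_labels = ["low", "middle", "high"]
    else:
        cuts = sorted(scheme.thresholds)
        default_labels = [f"s{i + 1}" for i in range(len(cuts) + 1)]
    labels = list(scheme.labels) if scheme.labels else default_labels
    if len(labels) != len(cuts) + 1:
        raise ValueError("need one label per stratum")
    bins = [-np.inf, *cuts, np.inf]
    return pd.cut(values, bins=bins, labels=labels, include_lowest=True)


def run_heterogeneity(
    data: pd.DataFrame, spec: RegressionSpec, scheme: SubgroupScheme
) -> dict[str, RegressionFit]:
    """Re-fit the main model within each stratum of a splitting variable.

    When the sample is split into income terciles, income is removed from
    the within-stratum regressor list (it is the splitting variable); any
    other split keeps the full regressor set.  Override with
    ``scheme.include_split_var``.
    """
    data = _prepare(data, spec)
    if scheme.variable not in data.columns:
        raise ValueError(f"splitting variable {scheme.variable!r} not in data")
    strata = _strata(data[scheme.variable], scheme)

    drop_split = scheme.variable == "income" and scheme.rule == "tercile"
    if scheme.include_split_var is not None:
        drop_split = not scheme.include_split_var
    sub_spec = spec
    if drop_split and scheme.variable in (*spec.focal, *spec.controls):
        sub_spec = RegressionSpec(
            outcome=spec.outcome,
            focal=tuple(t for t in spec.focal if t != scheme.variable),
            controls=tuple(t for t in spec.controls if t != scheme.variable),
            fixed_effect=spec.fixed_effect,
            cluster=spec.cluster,
            on_collinear=spec.on_collinear,
        )

    fits: dict[str, RegressionFit] = {}
    for label in strata.cat.categories:
        chunk = data[strata == label]
        if len(chunk) < scheme.min_n:
            raise ValueError(
                f"stratum {label!r} has {len(chunk)} rows < min_n={scheme.min_n}"
            )
        fit = fit_main_model(chunk, sub_spec)
        fit.stratum = str(label)
        fits[str(label)] = fit
    return fits


def heterogeneity_table(fits: Mapping[str, RegressionFit]) -> pd.DataFrame:
    """Stack per-stratum tidy tables in stratum order."""
    return pd.concat([f.table() for f in fits.values()], ignore_index=True)


# ---------------------------------------------------------------------------
# SUR


@dataclass
class SurSystem:
    """Feasible-GLS estimates of a multi-equation system."""

    outcomes: tuple[str, ...]
    params: pd.DataFrame  # term x equation
    se: pd.DataFrame
    sigma: pd.DataFrame  # residual cross-equation covariance
    cov: np.ndarray  # stacked-coefficient covariance
    terms: tuple[str, ...]
    n: int
    fgls: bool  # False = fell back to per-equation OLS

    def wald_joint(self, term: str) -> tuple[float, int, float]:
        """Chi-square Wald test that ``term``'s coefficient is zero in every
        equation; returns (statistic, df, p-value)."""
        from scipy import stats

        if term not in self.terms:
            raise ValueError(f"unknown regressor {term!r}")
        k = len(self.terms)
        j = self.terms.index(term)
        idx = [g * k + j for g in range(len(self.outcomes))]
        beta = self.params.loc[term].to_numpy(dtype=float)
        V = self.cov[np.ix_(idx, idx)]
        stat = float(beta @ np.linalg.solve(V, beta))
        df = len(self.outcomes)
        return stat, df, float(stats.chi2.sf(stat, df))


def fit_sur(
    data: pd.DataFrame,
    outcomes: Sequence[str],
    spec: RegressionSpec | None = None,
) -> SurSystem:
    """One-step feasible-GLS SUR across outcome equations sharing regressors.

    OLS residuals give the cross-equation covariance estimate; GLS then
    reweights.  With identical regressor matrices the GLS step reproduces
    per-equation OLS exactly (textbook equivalence).  A singular residual
    covariance triggers a fallback to per-equation OLS with a warning.
    """
    spec = spec or RegressionSpec(outcome=outcomes[0])
    G = len(outcomes)
    ys, Xs = [], []
    X_cols = None
    rows = None
    for out in outcomes:
        eq_spec = RegressionSpec(
            outcome=out, focal=spec.focal, controls=spec.controls,
            fixed_effect=spec.fixed_effect, cluster=None,
            on_collinear=spec.on_collinear,
        )
        y, X, _, _ = build_design(data, eq_spec)
        if rows is None:
            rows = y.index
            X_cols = tuple(X.columns)
        elif not y.index.equals(rows):
            raise ValueError("equations cover different rows; SUR needs a shared sample")
        ys.append(y.to_numpy(dtype=float))
        Xs.append(_resolve_collinearity(X, spec.on_collinear).to_numpy(dtype=float))
    n = len(rows)
    k = Xs[0].shape[1]
    if any(X.shape[1] != k for X in Xs):
        raise ValueError("collinearity handling produced unequal regressor sets")

    # stage 1: per-equation OLS residuals
    betas_ols = [np.linalg.lstsq(X, y, rcond=None)[0] for X, y in zip(Xs, ys)]
    E = np.column_stack([y - X @ b for X, y, b in zip(Xs, ys, betas_ols)])
    sigma = (E.T @ E) / n

    fgls = True
    try:
        S = np.linalg.inv(sigma)
        if not np.isfinite(S).all() or np.linalg.cond(sigma) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("singular residual covariance; falling back to per-equation OLS")
        fgls = False
        S = np.diag(1.0 / np.maximum(np.diag(sigma), 1e-300))

    # stage 2: GLS on the stacked system, assembled blockwise
    A = np.zeros((G * k, G * k))
    c = np.zeros(G * k)
    XtX = [[Xs[g].T @ Xs[h] for h in range(G)] for g in range(G)]
    Xty = [[Xs[g].T @ ys[h] for h in range(G)] for g in range(G)]
    for g in range(G):
        for h in range(G):
            A[g * k:(g + 1) * k, h * k:(h + 1) * k] = S[g, h] * XtX[g][h]
        c[g * k:(g + 1) * k] = sum(S[g, h] * Xty[g][h] for h in range(G))
    beta = np.linalg.solve(A, c)
    cov = np.linalg.inv(A)

    params = pd.DataFrame(
        beta.reshape(G, k).T, index=X_cols, columns=list(outcomes)
    )
    se = pd.DataFrame(
        np.sqrt(np.diag(cov)).reshape(G, k).T, index=X_cols, columns=list(outcomes)
    )
    return SurSystem(
        outcomes=tuple(outcomes),
        params=params,
        se=se,
        sigma=pd.DataFrame(sigma, index=list(outcomes), columns=list(outcomes)),
        cov=cov,
        terms=X_cols,
        n=n,
        fgls=fgls,
    )


# ---------------------------------------------------------------------------
# LASSO


@dataclass
class LassoFit:
    """L1-penalised fit with a cross-validated penalty.

    The penalty is expressed on the scale of the raw objective
    ``RSS + lambda * sum|beta|`` (no 1/n factor).  Coefficients are reported
    on the internal (standardized) scale and mapped back to the original
    predictor scale.
    """

    predictors: tuple[str, ...]
    lambdas: np.ndarray
    coef_path: np.ndarray  # p x n_lambda, standardized scale
    cv_error: np.ndarray
    cv_se: np.ndarray
    fold_assignment: np.ndarray
    lambda_min: float
    lambda_1se: float
    selected_lambda: float
    coef_std: pd.Series
    coef_original: pd.Series
    intercept: float

    @property
    def selected(self) -> list[str]:
        return [p for p, b in self.coef_std.items() if b != 0.0]


def _lasso_at(Xc: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    n = Xc.shape[0]
    if lam == 0.0:
        return np.linalg.lstsq(Xc, yc, rcond=None)[0]
    est = Lasso(alpha=lam / (2 * n), fit_intercept=False, max_iter=50_000, tol=1e-10)
    est.fit(Xc, yc)
    return est.coef_


def fit_lasso_cv(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    rule: str = "min",
    standardize: bool = True,
) -> LassoFit:
    """LASSO over a decreasing penalty grid with k-fold cross-validation.

    The grid runs from the smallest penalty that zeroes every slope
    (``lambda_max = 2 max_j |x_j'y|`` on the centered design) down by
    ``lambda_min_ratio``; fold assignment is a seeded permutation; the
    selected penalty minimises CV mean-squared error ("min") or is the
    largest within one standard error of the minimum ("1se").
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    data = data.dropna(subset=[outcome, *predictors])
    n = len(data)
    if n < folds:
        raise ValueError(f"only {n} complete rows for {folds} folds")

    X = data[list(predictors)].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    if standardize:
        if (x_sd == 0).any():
            bad = [p for p, s in zip(predictors, x_sd) if s == 0]
            raise ValueError(f"constant predictors cannot be standardized: {bad}")
        Xc = (X - x_mean) / x_sd
    else:
        Xc = X - x_mean
        x_sd = np.ones_like(x_sd)
    y_mean = y.mean()
    yc = y - y_mean

    lam_max = 2.0 * np.abs(Xc.T @ yc).max()
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(n) % folds)

    sq_err = np.zeros((folds, n_lambda))
    counts = np.zeros(folds)
    for f in range(folds):
        tr, va = fold != f, fold == f
        n_tr = int(tr.sum())
        # sklearn path alphas are (1/2n)-scaled versions of our lambda grid
        _, coefs, _ = lasso_path(
            Xc[tr], yc[tr], alphas=lambdas / (2 * n_tr), tol=1e-8, max_iter=10_000
        )
        pred = Xc[va] @ coefs  # n_va x n_lambda
        sq_err[f] = ((yc[va][:, None] - pred) ** 2).mean(axis=0)
        counts[f] = va.sum()
    cv_error = sq_err.mean(axis=0)
    cv_se = sq_err.std(axis=0, ddof=1) / np.sqrt(folds)

    i_min = int(np.argmin(cv_error))
    lambda_min = float(lambdas[i_min])
    within = cv_error <= cv_error[i_min] + cv_se[i_min]
    lambda_1se = float(lambdas[:i_min + 1][within[:i_min + 1]].max())
    selected = lambda_min if rule == "min" else lambda_1se

    _, path_coefs, _ = lasso_path(
        Xc, yc, alphas=lambdas / (2 * n), tol=1e-8, max_iter=10_000
    )
    coef_std = _lasso_at(Xc, yc, selected)
    coef_orig = coef_std / x_sd
    intercept = float(y_mean - coef_orig @ x_mean)
    return LassoFit(
        predictors=tuple(predictors),
        lambdas=lambdas,
        coef_path=path_coefs,
        cv_error=cv_error,
        cv_se=cv_se,
        fold_assignment=fold,
        lambda_min=lambda_min,
        lambda_1se=lambda_1se,
        selected_lambda=float(selected),
        coef_std=pd.Series(coef_std, index=list(predictors)),
        coef_original=pd.Series(coef_orig, index=list(predictors)),
        intercept=intercept,
    )
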