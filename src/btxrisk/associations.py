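"""Regression layer: paired change tests, adjusted decline models,
stratified analyses and effect-modification (interaction) tests.

All fits are ordinary least squares through statsmodels; the exposure
coefficient is the change in a parameter's decline per unit ln-CE
(ln mg/m3 x year), with covariate adjustment.  Group comparisons of the
decline ("covariance analysis") are OLS with a group indicator plus
covariates, reported as adjusted means at the covariate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    analyte: str
    beta: float
    ci95: tuple[float, float]
    p_trend: float
    n: int
    stratum: str | None = None
    p_interaction: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.beta <= self.ci95[1]):
            raise ValueError("confidence interval must contain the point estimate")


def paired_change_test(baseline, follow_up) -> tuple[float, float, float]:
    """Paired t-test on baseline minus follow-up differences.

    Returns (mean decline, t statistic, two-sided p).  Zero-variance
    differences (a constant shift) leave the t statistic undefined and are
    an error.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(follow_up, dtype=float)
    if b.shape != f.shape or b.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    d = b - f
    if np.ptp(d) == 0:
        raise ValueError("differences have zero variance; paired t undefined")
    t, p = stats.ttest_rel(b, f)
    return float(d.mean()), float(t), float(p)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X.to_numpy(dtype=float))
        small = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8] if r.shape[0] >= X.shape[1] else list(X.columns)
        raise ValueError(f"design matrix rank deficient; collinear columns include {small}")


def adjusted_decline_model(
    decline,
    ln_ce,
    covariates: pd.DataFrame | None = None,
    outcome: str = "",
    analyte: str = "",
) -> RegressionResult:
    """Covariate-adjusted OLS of a parameter's decline on ln-CE.

    beta is the ln-CE coefficient; p_trend its Wald p-value.
    """
    y = np.asarray(decline, dtype=float)
    X = pd.DataFrame({"const": 1.0, "ln_ce": np.asarray(ln_ce, dtype=float)})
    if covariates is not None and len(covariates.columns):
        X = pd.concat([X.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["ln_ce"]
    return RegressionResult(
        outcome=outcome,
        analyte=analyte,
        beta=float(fit.params["ln_ce"]),
        ci95=(float(ci[0]), float(ci[1])),
        p_trend=float(fit.pvalues["ln_ce"]),
        n=int(y.size),
    )


def stratified_with_interaction(
    decline,
    ln_ce,
    covariates: pd.DataFrame | None,
    stratum,
    outcome: str = "",
    analyte: str = "",
) -> tuple[list[RegressionResult], float]:
    """Per-stratum exposure effects plus a pooled interaction test.

    Fits the adjusted decline model separately within each stratum, then a
    pooled model with a ln-CE x stratum product term; p_interaction is the
    Wald p of the product term (joint F when the stratum has more than two
    levels).
    """
    y = np.asarray(decline, dtype=float)
    x = np.asarray(ln_ce, dtype=float)
    s = pd.Series(stratum).reset_index(drop=True)
    levels = sorted(s.unique(), key=str)
    if len(levels) < 2:
        raise ValueError("need at least 2 strata for an interaction analysis")
    cov = None if covariates is None else covariates.reset_index(drop=True)

    per_stratum: list[RegressionResult] = []
    for lev in levels:
        mask = (s == lev).to_numpy()
        cov_s = None
        if cov is not None:
            cov_s = cov.loc[mask]
            # drop stratum-constant covariates (e.g. the stratifier itself)
            keep = [c for c in cov_s.columns if cov_s[c].nunique() > 1]
            cov_s = cov_s[keep]
        n_params = 2 + (0 if cov_s is None else cov_s.shape[1])
        if mask.sum() <= n_params:
            raise ValueError(f"stratum {lev!r} has n={int(mask.sum())} <= {n_params} parameters")
        res = adjusted_decline_model(y[mask], x[mask], cov_s, outcome, analyte)
        per_stratum.append(
            RegressionResult(res.outcome, res.analyte, res.beta, res.ci95, res.p_trend, res.n, stratum=str(lev))
        )

    # pooled model with product term(s)
    X = pd.DataFrame({"const": 1.0, "ln_ce": x})
    inter_cols = []
    for lev in levels[1:]:
        ind = (s == lev).astype(float).to_numpy()
        X[f"stratum_{lev}"] = ind
        col = f"ln_ce_x_{lev}"
        X[col] = x * ind
        inter_cols.append(col)
    if cov is not None and len(cov.columns):
        X = pd.concat([X, cov], axis=1)
    _check_full_rank(X)
    pooled = sm.OLS(y, X).fit()
    if len(inter_cols) == 1:
        p_int = float(pooled.pvalues[inter_cols[0]])
    else:
        p_int = float(pooled.f_test([f"{c} = 0" for c in inter_cols]).pvalue)
    per_stratum = [
        RegressionResult(r.outcome, r.analyte, r.beta, r.ci95, r.p_trend, r.n, r.stratum, p_int)
        for r in per_stratum
    ]
    return per_stratum, p_int


def adjusted_group_means(
    decline,
    group,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted mean decline per group (ANCOVA-style).

    OLS with group indicators plus covariates; each group's adjusted mean is
    evaluated at the covariate means.  Returns a frame with columns
    ``group, adjusted_mean, se`` plus the overall group-effect p-value in
    ``attrs['p_group']``.
    """
    y = np.asarray(decline, dtype=float)
    g = pd.Series(group).reset_index(drop=True).astype(str)
    levels = sorted(g.unique())
    X = pd.DataFrame({"const": np.ones(len(g))})
    for lev in levels[1:]:
        X[f"group_{lev}"] = (g == lev).astype(float)
    cov_means = {}
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True)
        cov_means = cov.mean().to_dict()
        X = pd.concat([X, cov], axis=1)
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit()
    rows = []
    for lev in levels:
        vec = pd.Series(0.0, index=X.columns)
        vec["const"] = 1.0
        if lev != levels[0]:
            vec[f"group_{lev}"] = 1.0
        for c, m in cov_means.items():
            vec[c] = m
        v = vec.to_numpy()
        mean = float(v @ fit.params.to_numpy())
        se = float(np.sqrt(v @ fit.cov_params().to_numpy() @ v))
        rows.append({"group": lev, "adjusted_mean": mean, "se": se})
    out = pd.DataFrame(rows)
    if len(levels) > 1:
        out.attrs["p_group"] = float(
            fit.f_test([f"group_{lev} = 0" for lev in levels[1:]]).pvalue
        )
    return out


def tertile_labels(values) -> np.ndarray:
    """Low/medium/high labels from tertiles (interpolated quantile rule)."""
    from .exposure import quantile_score

    score = quantile_score(values, q=3)
    return np.array(["low", "medium", "high"])[score]
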