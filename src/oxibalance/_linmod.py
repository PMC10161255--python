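"""Internal least-squares machinery shared by the GRS, OBS and association stages.

All biomarker models are ordinary least squares on natural-log FiP.
Adjusted (covariate-standardized) geometric means are exponentiated
least-squares means: the fitted category mean evaluated with every
covariate held at its analytic-sample mean (categorical covariates at
their observed proportions, via centered dummies).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._errors import ModelError


def build_covariate_matrix(covariates: pd.DataFrame | None, index) -> pd.DataFrame:
    """Expand a covariate frame to numeric columns (dummies for categoricals)."""
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return pd.DataFrame(index=index)
    cov = pd.DataFrame(covariates).copy()
    if len(cov) != len(index):
        raise ModelError(
            f"covariate table has {len(cov)} rows, expected {len(index)}"
        )
    cov.index = index  # align positionally with the outcome/labels
    out = {}
    for col in cov.columns:
        s = cov[col]
        if s.dtype == bool or str(s.dtype) == "boolean":
            out[col] = s.astype(float)
        elif s.dtype.kind in "ifu":
            out[col] = s.astype(float)
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            for dcol in dummies.columns:
                out[dcol] = dummies[dcol].astype(float)
    return pd.DataFrame(out, index=index)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns involved in the dependency for the error message
        bad = []
        cols = list(X.columns)
        for j in range(X.shape[1]):
            sub = X.drop(columns=[cols[j]])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                bad.append(cols[j])
        raise ModelError(f"singular design matrix; collinear terms include: {bad}")


def fit_category_model(
    log_y: pd.Series,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference=None,
):
    """OLS of log outcome on category indicators plus covariates.

    Returns a dict with the fitted results, the per-category adjusted
    geometric means (exp of least-squares means at covariate means), the
    95% CI, and the per-category contrast p versus the reference.
    """
    labels = pd.Series(labels)
    log_y = pd.Series(np.asarray(log_y, dtype=float), index=labels.index)
    cov = build_covariate_matrix(covariates, labels.index)
    keep = log_y.notna() & labels.notna()
    if len(cov.columns):
        keep &= cov.notna().all(axis=1)
    log_y, labels, cov = log_y[keep], labels[keep], cov.loc[keep]

    cats = sorted(labels.unique())
    if reference is None:
        reference = cats[0]
    if reference not in cats:
        raise ModelError(f"reference category {reference!r} not present")
    empty = [c for c in cats if (labels == c).sum() == 0]
    if empty:
        raise ModelError(f"empty categories: {empty}")

    dummies = pd.get_dummies(labels, prefix="cat").astype(float)
    dummy_cols = {c: f"cat_{c}" for c in cats}
    X = pd.concat(
        [dummies.drop(columns=[dummy_cols[reference]]), cov], axis=1
    )
    X = sm.add_constant(X, has_constant="add")
    _check_full_rank(X)
    fit = sm.OLS(log_y, X).fit()

    cov_means = cov.mean(axis=0)
    dfres = int(fit.df_resid)
    tq = stats.t.ppf(0.975, dfres) if dfres > 0 else np.nan
    rows = []
    for c in cats:
        x = pd.Series(0.0, index=X.columns)
        x["const"] = 1.0
        if c != reference:
            x[dummy_cols[c]] = 1.0
        for name, m in cov_means.items():
            x[name] = m
        xv = x.to_numpy()
        lsmean = float(xv @ fit.params.to_numpy())
        se = float(np.sqrt(xv @ fit.cov_params().to_numpy() @ xv))
        p = np.nan if c == reference else float(fit.pvalues[dummy_cols[c]])
        coef = 0.0 if c == reference else float(fit.params[dummy_cols[c]])
        rows.append(
            {
                "category": c,
                "n": int((labels == c).sum()),
                "lsmean": lsmean,
                "se": se,
                "geometric_mean": float(np.exp(lsmean)),
                "ci_low": float(np.exp(lsmean - tq * se)),
                "ci_high": float(np.exp(lsmean + tq * se)),
                "log_contrast": coef,
                "p_vs_ref": p,
            }
        )
    return {
        "fit": fit,
        "table": pd.DataFrame(rows),
        "reference": reference,
        "labels": labels,
        "covariates": cov,
        "log_y": log_y,
    }


def trend_pvalue(log_y, numeric_score, covariates=None) -> float:
    """P-value for a linear (ordinal) trend of log outcome on a score."""
    numeric_score = pd.Series(numeric_score)
    log_y = pd.Series(np.asarray(log_y, float), index=numeric_score.index)
    cov = build_covariate_matrix(covariates, numeric_score.index)
    keep = log_y.notna() & numeric_score.notna()
    if len(cov.columns):
        keep &= cov.notna().all(axis=1)
    X = pd.concat([numeric_score[keep].rename("score").astype(float), cov.loc[keep]], axis=1)
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(log_y[keep], X).fit()
    return float(fit.pvalues["score"])
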