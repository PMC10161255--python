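"""Category construction and adjusted geometric-mean FiP comparisons.

Scores are cut into tertiles at the empirical 1/3 and 2/3 quantiles
with ties unsplit (tied values share one category, hence unequal
tertile sizes for integer scores), or dichotomized at a configured
integer cutpoint (low < cutpoint <= high).  Category models are OLS on
natural-log FiP; adjusted geometric means, 95% CIs and proportional
differences versus the reference category come from exponentiated
least-squares means at covariate means.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._errors import ConfigurationError, ModelError
from ._linmod import build_covariate_matrix, fit_category_model, trend_pvalue
from .grs import proportional_difference


@dataclass(frozen=True)
class CategorySpec:
    """How a score is categorized for analysis."""

    scheme: str = "tertile"  # "tertile" | "dichotomy"
    cutpoint: float | None = None  # dichotomy: low < cutpoint <= high


def assign_categories(scores, spec: CategorySpec = CategorySpec()):
    """Assign category labels (1-based) and per-category score medians.

    Tertiles: categories are 1 + (s > q1) + (s > q2) for the empirical
    1/3 and 2/3 quantiles, so all copies of a tied value land in the
    same category.  Dichotomy: 1 (low) if s < cutpoint else 2 (high).
    """
    scores = pd.Series(scores).astype(float)
    if scores.isna().any():
        raise ConfigurationError("scores contain missing values; filter first")
    if spec.scheme == "tertile":
        if scores.nunique() < 3:
            raise ConfigurationError(
                f"only {scores.nunique()} distinct score values; cannot form tertiles"
            )
        q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
        labels = 1 + (scores > q1).astype(int) + (scores > q2).astype(int)
    elif spec.scheme == "dichotomy":
        if spec.cutpoint is None:
            raise ConfigurationError("dichotomy requires a cutpoint")
        if scores.nunique() < 2:
            raise ConfigurationError("fewer than 2 distinct score values")
        labels = np.where(scores < spec.cutpoint, 1, 2)
        labels = pd.Series(labels, index=scores.index)
        if labels.nunique() < 2:
            raise ConfigurationError(
                f"cutpoint {spec.cutpoint} leaves an empty category"
            )
    else:
        raise ConfigurationError(f"unknown scheme {spec.scheme!r}")
    labels.name = "category"
    medians = scores.groupby(labels).median().to_dict()
    return labels, medians


def adjusted_means_by_category(
    fip,
    categories,
    covariates: pd.DataFrame | None = None,
    score_medians: dict | None = None,
) -> pd.DataFrame:
    """Adjusted geometric-mean FiP per category with CIs and contrasts.

    Returns one row per category: n, adjusted geometric mean, 95% CI,
    proportional difference versus the reference (lowest) category, and
    the contrast p-value; ``attrs`` carry the highest-vs-reference
    contrast p (``p_contrast``) and, when score medians are supplied, a
    median-scored ordinal trend p (``p_trend``).
    """
    fip = pd.Series(np.asarray(fip, float))
    if (fip.dropna() <= 0).any():
        raise ConfigurationError("FiP must be positive")
    categories = pd.Series(categories).reset_index(drop=True)
    res = fit_category_model(np.log(fip.values), categories, covariates=covariates)
    table = res["table"]
    ref_gm = float(table["geometric_mean"].iloc[0])
    table["prop_diff"] = [
        0.0 if i == 0 else proportional_difference(gm, ref_gm)
        for i, gm in enumerate(table["geometric_mean"])
    ]
    table["prop_diff_label"] = [
        "Ref." if i == 0 else f"{pdv:.1f}" for i, pdv in enumerate(table["prop_diff"])
    ]
    if score_medians is not None:
        table.insert(1, "score_median", [score_medians.get(c, np.nan) for c in table["category"]])
        numeric = categories.map(score_medians)
        table.attrs["p_trend"] = trend_pvalue(np.log(fip.values), numeric, covariates)
    table.attrs["p_contrast"] = float(table["p_vs_ref"].iloc[-1])
    return table


def _interaction_pvalues(log_y, strat_labels, ordinal, covariates):
    """Wald p for stratum x score interaction (ordinal and dummy codings)."""
    strat = pd.Series(strat_labels).reset_index(drop=True)
    ordinal = pd.Series(ordinal).reset_index(drop=True).astype(float)
    y = pd.Series(np.asarray(log_y, float))
    cov = build_covariate_matrix(covariates, strat.index)
    hi = (strat == strat.max()).astype(float)

    keep = y.notna() & ordinal.notna()
    if len(cov.columns):
        keep &= cov.notna().all(axis=1)

    X = pd.DataFrame({"stratum_hi": hi, "score_ord": ordinal})
    X["stratum_hi:score_ord"] = X["stratum_hi"] * X["score_ord"]
    X = pd.concat([X, cov], axis=1).loc[keep]
    fit = sm.OLS(y[keep], sm.add_constant(X, has_constant="add")).fit()
    p_ordinal = float(fit.pvalues["stratum_hi:score_ord"])

    dummies = pd.get_dummies(ordinal, prefix="lvl", drop_first=True).astype(float)
    Xd = pd.DataFrame({"stratum_hi": hi})
    inter_cols = []
    for c in dummies.columns:
        Xd[c] = dummies[c]
        Xd[f"hi:{c}"] = hi * dummies[c]
        inter_cols.append(f"hi:{c}")
    Xd = pd.concat([Xd, cov], axis=1).loc[keep]
    fitd = sm.OLS(y[keep], sm.add_constant(Xd, has_constant="add")).fit()
    constraint = ", ".join(f"{c} = 0" for c in inter_cols)
    p_dummy = float(np.squeeze(fitd.f_test(constraint).pvalue))
    return p_ordinal, p_dummy


def stratified_association(
    fip,
    obs_categories,
    grs_dichotomy,
    covariates: pd.DataFrame | None = None,
    obs_score_medians_by_stratum: dict | None = None,
) -> dict:
    """OBS-category models within each GRS stratum, plus interaction p.

    Fits the adjusted category model separately inside the low and high
    GRS strata, then a pooled model with a (GRS stratum) x (ordinal
    OBS category, 1..k) interaction term whose two-sided Wald p is the
    headline ``p_interaction``; a dummy-coded interaction F-test is
    reported alongside as ``p_interaction_dummy``.
    """
    fip = pd.Series(np.asarray(fip, float))
    obs_categories = pd.Series(obs_categories).reset_index(drop=True)
    grs_dichotomy = pd.Series(grs_dichotomy).reset_index(drop=True)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
    strata = {}
    for level in sorted(grs_dichotomy.unique()):
        mask = (grs_dichotomy == level).values
        present = set(obs_categories[mask].unique())
        expected = set(obs_categories.unique())
        if present != expected:
            raise ModelError(
                f"GRS stratum {level!r}: empty OBS categories {sorted(expected - present)}"
            )
        cov = covariates[mask] if covariates is not None else None
        medians = (
            obs_score_medians_by_stratum.get(level)
            if obs_score_medians_by_stratum
            else None
        )
        strata[level] = adjusted_means_by_category(
            fip[mask].values,
            obs_categories[mask].values,
            covariates=cov.reset_index(drop=True) if cov is not None else None,
            score_medians=medians,
        )
    p_ord, p_dummy = _interaction_pvalues(
        np.log(fip.values), grs_dichotomy, obs_categories, covariates
    )
    return {"strata": strata, "p_interaction": p_ord, "p_interaction_dummy": p_dummy}


def joint_grs_analysis(
    fip, ae_dichotomy, ber_dichotomy, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Four-cell joint AE x BER analysis, joint-low cell as reference.

    Cells are (AE low/high) x (BER low/high); each non-reference cell
    carries its adjusted geometric mean, CI, proportional difference and
    contrast p versus the joint-low cell.
    """
    ae = pd.Series(ae_dichotomy).reset_index(drop=True)
    ber = pd.Series(ber_dichotomy).reset_index(drop=True)
    name = {1: "low", 2: "high"}
    cells = pd.Series(
        [f"AE_{name.get(a, a)}/BER_{name.get(b, b)}" for a, b in zip(ae, ber)],
        index=ae.index,
    )
    expected = [f"AE_{a}/BER_{b}" for a in ("low", "high") for b in ("low", "high")]
    missing = [c for c in expected if c not in set(cells)]
    if missing:
        raise ModelError(f"empty joint GRS cells: {missing}")
    order = {c: i for i, c in enumerate(expected)}
    res = fit_category_model(
        np.log(np.asarray(fip, float)), cells.map(order), covariates=covariates, reference=0
    )
    table = res["table"]
    table["category"] = [expected[int(c)] for c in table["category"]]
    table = table.set_index("category").loc[expected].reset_index()
    ref_gm = float(table.loc[0, "geometric_mean"])
    table["prop_diff"] = [
        0.0 if i == 0 else proportional_difference(gm, ref_gm)
        for i, gm in enumerate(table["geometric_mean"])
    ]
    return table


def plot_joint_analysis(table: pd.DataFrame, path=None):
    """Bar chart of the four joint-cell adjusted geometric means with CIs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(table))
    gm = table["geometric_mean"]
    err = np.vstack([gm - table["ci_low"], table["ci_high"] - gm])
    ax.bar(x, gm, yerr=err, capsize=4, color="#4878a8")
    ax.set_xticks(x, table["category"], rotation=20, ha="right")
    ax.set_ylabel("Adjusted geometric mean FiP (pg/mL)")
    ax.set_xlabel("Joint AE/BER GRS category")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
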