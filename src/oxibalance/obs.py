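"""Biomarker-weighted oxidative balance score (OBS).

Continuous diet components are standardized to mean 0, SD 1 within
study-sex strata; categorical lifestyle components enter as dummy
variables against a referent level.  One multivariable OLS of
natural-log FiP on all components jointly yields the per-component
beta coefficients; each component's weight is 10 x beta.  The score is
the negated weighted sum, so that a higher OBS corresponds to a lower
model-predicted FiP — i.e. a predominance of antioxidant over
pro-oxidant exposures.  The negation is the package's reading of the
"weights = 10 x beta, higher score = antioxidant predominance"
convention: summing +10 x beta-weighted values would orient the score
the other way; it can be switched off (``negate=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from ._errors import ConfigurationError, ModelError
from ._linmod import _check_full_rank

logger = logging.getLogger(__name__)


def standardize_component(values, study, sex) -> pd.Series:
    """Z-score a component within each study-sex stratum (sample SD, n-1).

    Raises when a stratum has fewer than two distinct values (zero SD),
    naming the stratum.
    """
    values = pd.Series(np.asarray(values, float))
    study = pd.Series(study).reset_index(drop=True)
    sex = pd.Series(sex).reset_index(drop=True)
    out = pd.Series(np.nan, index=values.index)
    for (st, sx), idx in values.groupby([study, sex]).groups.items():
        v = values.loc[idx]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ModelError(
                f"component has zero within-stratum SD in stratum (study={st}, sex={sx})"
            )
        out.loc[idx] = (v - v.mean()) / sd
    return out


@dataclass
class ObsWeightSet:
    """Fitted component weights: weight = scale x beta (referent levels 0)."""

    weights: pd.DataFrame  # columns: component, level, beta, weight
    scale: float
    diagnostics: dict

    def weight_for(self, column: str) -> float:
        m = self.weights["column"] == column
        return float(self.weights.loc[m, "weight"].iloc[0])


def _vif(X: pd.DataFrame) -> pd.Series:
    out = {}
    arr = X.to_numpy()
    for j, col in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        others = np.column_stack([np.ones(len(X)), others])
        beta, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
        resid = arr[:, j] - others @ beta
        tss = np.sum((arr[:, j] - arr[:, j].mean()) ** 2)
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        out[col] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out)


def fit_obs_weights(
    standardized: pd.DataFrame,
    lifestyle_dummies: pd.DataFrame | None,
    ln_fip,
    scale: float = 10.0,
) -> ObsWeightSet:
    """Estimate component weights from one joint multivariable model.

    ``standardized``: stratum-standardized continuous components;
    ``lifestyle_dummies``: 0/1 indicators for non-referent categorical
    levels (columns named ``component__level``).  Returns weights =
    ``scale`` x beta, plus condition-number and VIF diagnostics.
    """
    parts = [pd.DataFrame(standardized).astype(float)]
    if lifestyle_dummies is not None and len(lifestyle_dummies.columns):
        parts.append(pd.DataFrame(lifestyle_dummies).astype(float))
    X = pd.concat(parts, axis=1)
    y = pd.Series(np.asarray(ln_fip, float), index=X.index)
    keep = y.notna() & X.notna().all(axis=1)
    X, y = X.loc[keep], y[keep]
    Xc = sm.add_constant(X, has_constant="add")
    _check_full_rank(Xc)
    fit = sm.OLS(y, Xc).fit()

    diagnostics = {
        "condition_number": float(np.linalg.cond(Xc.to_numpy())),
        "vif": _vif(X),
        "n": int(len(y)),
        "r_squared": float(fit.rsquared),
    }
    logger.info(
        "OBS weight model: n=%d, R^2=%.3f, condition number %.1f",
        diagnostics["n"],
        fit.rsquared,
        diagnostics["condition_number"],
    )
    rows = []
    ci = fit.conf_int()
    for col in X.columns:
        comp, _, level = col.partition("__")
        rows.append(
            {
                "component": comp,
                "level": level or "per_sd",
                "column": col,
                "beta": float(fit.params[col]),
                "se": float(fit.bse[col]),
                "ci_low": float(ci.loc[col, 0]),
                "ci_high": float(ci.loc[col, 1]),
                "p": float(fit.pvalues[col]),
                "weight": scale * float(fit.params[col]),
            }
        )
    return ObsWeightSet(pd.DataFrame(rows), scale, diagnostics)


def compute_obs(
    standardized: pd.DataFrame,
    lifestyle_dummies: pd.DataFrame | None,
    weights: ObsWeightSet,
    negate: bool = True,
) -> pd.Series:
    """Sum the weighted component values into the per-participant score.

    OBS_i = -(sum_j weight_j x_ij) under the default orientation, so a
    higher score predicts a lower FiP.  Participants missing any
    component are scored missing.
    """
    parts = [pd.DataFrame(standardized).astype(float)]
    if lifestyle_dummies is not None and len(lifestyle_dummies.columns):
        parts.append(pd.DataFrame(lifestyle_dummies).astype(float))
    X = pd.concat(parts, axis=1)
    missing_cols = set(weights.weights["column"]) - set(X.columns)
    if missing_cols:
        raise ConfigurationError(
            f"component columns absent from the input: {sorted(missing_cols)}"
        )
    w = weights.weights.set_index("column")["weight"]
    score = X[w.index].to_numpy() @ w.to_numpy()
    score = pd.Series(score, index=X.index, name="obs")
    score[X[w.index].isna().any(axis=1)] = np.nan
    return -score if negate else score


def make_lifestyle_dummies(df: pd.DataFrame, components: dict) -> pd.DataFrame:
    """0/1 indicators for every non-referent categorical level.

    ``components`` maps component name to its ordered level tuple (first
    level = referent); column names are ``component__level``.
    """
    out = {}
    for name, levels in components.items():
        s = df[name].astype(str)
        for level in levels[1:]:
            out[f"{name}__{level}"] = (s == level).astype(float)
        out_missing = ~s.isin([str(l) for l in levels])
        for level in levels[1:]:
            out[f"{name}__{level}"][out_missing] = np.nan
    return pd.DataFrame(out, index=df.index)


class ObsScorer(BaseEstimator, TransformerMixin):
    """Biomarker-weighted oxidative balance score, scikit-learn style.

    ``fit(X, y)`` expects ``X`` to carry ``study`` and ``sex`` columns,
    the continuous component columns, and the categorical component
    columns; ``y`` is FiP (pg/mL).  Standardization statistics
    (per-stratum means/SDs) and fitted weights are stored so that
    ``transform`` can score new cohorts on the training scale.

    Parameters
    ----------
    continuous : sequence of str, optional
        Continuous component columns (default: inferred as the numeric
        columns among the known component names).
    categorical : dict, optional
        Mapping of categorical component name to ordered level tuple
        (first level referent).
    scale : float, default 10
        Cosmetic weight scale factor (weight = scale x beta).
    negate : bool, default True
        Orient the score so higher = antioxidant predominance.

    Attributes
    ----------
    weights_ : ObsWeightSet
    strata_stats_ : DataFrame of per-stratum component means and SDs.
    """

    def __init__(self, continuous=None, categorical=None, scale: float = 10.0, negate: bool = True):
        self.continuous = continuous
        self.categorical = categorical
        self.scale = scale
        self.negate = negate

    def _resolve_components(self, X: pd.DataFrame):
        from .simulate import CATEGORICAL_COMPONENTS, CONTINUOUS_COMPONENTS

        continuous = (
            list(self.continuous)
            if self.continuous is not None
            else [c for c in CONTINUOUS_COMPONENTS if c in X.columns]
        )
        if self.categorical is not None:
            categorical = dict(self.categorical)
        else:
            categorical = {
                c: tuple(pd.Series(X[c]).dropna().astype(str).unique())
                for c in CATEGORICAL_COMPONENTS
                if c in X.columns
            }
            categorical = {c: tuple(sorted(v)) for c, v in categorical.items()}
        if not continuous and not categorical:
            raise ConfigurationError("no OBS component columns found in X")
        return continuous, categorical

    def _standardize(self, X: pd.DataFrame, training: bool) -> pd.DataFrame:
        out = {}
        strata = list(zip(X["study"].astype(str), X["sex"].astype(str)))
        key = pd.Series([f"{st}|{sx}" for st, sx in strata], index=X.index)
        if training:
            stats_rows = []
            for comp in self.continuous_:
                v = pd.Series(np.asarray(X[comp], float), index=X.index)
                z = pd.Series(np.nan, index=X.index)
                for stratum, idx in v.groupby(key).groups.items():
                    sd = v.loc[idx].std(ddof=1)
                    if not np.isfinite(sd) or sd == 0:
                        raise ModelError(
                            f"{comp}: zero within-stratum SD in stratum {stratum}"
                        )
                    m = v.loc[idx].mean()
                    z.loc[idx] = (v.loc[idx] - m) / sd
                    stats_rows.append(
                        {"component": comp, "stratum": stratum, "mean": m, "sd": sd}
                    )
                out[comp] = z
            self.strata_stats_ = pd.DataFrame(stats_rows)
        else:
            stats = self.strata_stats_.set_index(["component", "stratum"])
            for comp in self.continuous_:
                v = pd.Series(np.asarray(X[comp], float), index=X.index)
                z = pd.Series(np.nan, index=X.index)
                for stratum, idx in v.groupby(key).groups.items():
                    try:
                        m = stats.loc[(comp, stratum), "mean"]
                        sd = stats.loc[(comp, stratum), "sd"]
                    except KeyError as exc:
                        raise ConfigurationError(
                            f"stratum {stratum} was not seen during fit"
                        ) from exc
                    z.loc[idx] = (v.loc[idx] - m) / sd
                out[comp] = z
        return pd.DataFrame(out, index=X.index)


    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        for col in ("study", "sex"):
            if col not in X.columns:
                raise ConfigurationError(f"X must carry a {col!r} column")
        y = np.asarray(y, dtype=float)
        if (y[np.isfinite(y)] <= 0).any():
            raise ConfigurationError("FiP must be positive")
        self.continuous_, self.categorical_ = self._resolve_components(X)
        z = self._standardize(X, training=True)
        dummies = make_lifestyle_dummies(X, self.categorical_)
        self.weights_ = fit_obs_weights(z, dummies, np.log(y), scale=self.scale)
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "weights_"):
            raise ModelError("ObsScorer is not fitted")
        X = pd.DataFrame(X)
        z = self._standardize(X, training=False)
        dummies = make_lifestyle_dummies(X, self.categorical_)
        return compute_obs(z, dummies, self.weights_, negate=self.negate)
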