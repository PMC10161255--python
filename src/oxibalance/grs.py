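"""Genetic risk score construction.

Per-SNP covariate-adjusted geometric-mean FiP comparisons, proportional
differences versus the common homozygote, pathway-specific selection
thresholds, and signed allele-count scoring.  The selection rule pairs a
magnitude condition on the proportional difference with a p-value
condition; defaults follow the pathway-specific pilot criteria
(antioxidant enzymes: >5% with p<=0.05 or >10% with p<=0.15; base
excision repair: >10% with p<=0.15), applied to |proportional
difference| so inversely associated variants enter with negative sign.

The :class:`GrsScorer` estimator wraps the full sequence (QC, collapse,
per-genotype means, selection, scoring) in a scikit-learn fit/transform
interface; the module-level functions are the individual steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from ._errors import ConfigurationError, ModelError
from ._linmod import fit_category_model
from .qc import GenotypeCoding, collapse_sparse_genotypes, genotype_counts, hwe_exact_test

logger = logging.getLogger(__name__)


def proportional_difference(comparison_mean: float, reference_mean: float) -> float:
    """Percent difference of a comparison mean versus a reference mean.

    (comparison - reference) / reference x 100; report to one decimal.
    """
    if reference_mean <= 0:
        raise ConfigurationError(f"reference mean must be positive, got {reference_mean}")
    return (comparison_mean - reference_mean) / reference_mean * 100.0


@dataclass(frozen=True)
class SelectionRule:
    """Disjunctive selection criteria: (min |prop. diff| %, max p) pairs.

    A variant category qualifies if ANY pair is satisfied with strict
    inequality on the magnitude and non-strict on the p-value.
    """

    criteria: tuple

    def qualifies(self, prop_diff: float, p: float) -> bool:
        if not np.isfinite(prop_diff) or not np.isfinite(p):
            return False
        return any(abs(prop_diff) > d and p <= a for d, a in self.criteria)


DEFAULT_SELECTION_RULES = {
    "AE": SelectionRule(((5.0, 0.05), (10.0, 0.15))),
    "BER": SelectionRule(((10.0, 0.15),)),
}

_CATEGORY_OF_DOSAGE = {
    "dosage": {0: "common_hom", 1: "het", 2: "var_hom"},
    "carrier": {0: "common_hom", 1: "carrier", 2: "carrier"},
}


def adjusted_genotype_means(
    dosages,
    fip,
    sex=None,
    bmi=None,
    coding: GenotypeCoding | None = None,
    snp_id: str = "",
) -> pd.DataFrame:
    """Sex- and BMI-adjusted geometric mean FiP per genotype category.

    Fits OLS of natural-log FiP on genotype-category indicators plus the
    covariates; adjusted geometric means are exponentiated least-squares
    means at covariate means, and each variant category carries the
    two-sided t-test p of its contrast against the common homozygote.
    Complete-case: rows with missing genotype, FiP or covariates drop.
    """
    dosages = pd.Series(dosages).reset_index(drop=True)
    fip = pd.Series(np.asarray(fip, float), index=dosages.index)
    if (fip.dropna() <= 0).any():
        raise ConfigurationError("FiP must be positive")
    if coding is None:
        coding = collapse_sparse_genotypes(genotype_counts(dosages), snp_id=snp_id)
    mapping = _CATEGORY_OF_DOSAGE[coding.coding_mode]
    labels = dosages.map(lambda d: mapping.get(int(d)) if pd.notna(d) else np.nan)

    observed = [c for c in coding.categories if (labels == c).any()]
    dropped = [c for c in coding.categories if c not in observed]
    if dropped:
        warnings.warn(f"{snp_id or 'SNP'}: empty genotype categories dropped: {dropped}")
    if "common_hom" not in observed:
        raise ModelError(f"{snp_id or 'SNP'}: no common-homozygote reference group")

    covariates = {}
    if sex is not None:
        covariates["sex"] = pd.Series(sex, index=dosages.index).astype(str)
    if bmi is not None:
        covariates["bmi"] = pd.Series(np.asarray(bmi, float), index=dosages.index)
    cov_df = pd.DataFrame(covariates, index=dosages.index) if covariates else None

    res = fit_category_model(np.log(fip), labels, covariates=cov_df, reference="common_hom")
    table = res["table"]
    ref_gm = float(
        table.loc[table["category"] == "common_hom", "geometric_mean"].iloc[0]
    )
    # report in the coding's category order, reference first
    table = table.set_index("category").loc[[c for c in coding.categories if c in observed]]
    rows = []
    for cat, r in table.iterrows():
        pd_pct = 0.0 if cat == "common_hom" else proportional_difference(
            r["geometric_mean"], ref_gm
        )
        rows.append(
            {
                "snp": snp_id,
                "category": cat,
                "coding_mode": coding.coding_mode,
                "n": r["n"],
                "adj_geometric_mean": r["geometric_mean"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "prop_diff": pd_pct,
                "p": r["p_vs_ref"],
                "sign": 1 if pd_pct > 0 else (-1 if pd_pct < 0 else 0),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GrsDefinition:
    """A trained risk-score definition: signed SNPs and their coding."""

    pathway: str
    entries: list = field(default_factory=list)  # (snp_id, sign, coding_mode)
    selection_rule: SelectionRule | None = None

    def __len__(self):
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["snp", "sign", "coding_mode"])

    def save(self, path) -> None:
        doc = {
            "pathway": self.pathway,
            "entries": [list(e) for e in self.entries],
            "selection_rule": [list(c) for c in self.selection_rule.criteria]
            if self.selection_rule
            else None,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def load(cls, path) -> "GrsDefinition":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        rule = (
            SelectionRule(tuple(tuple(c) for c in doc["selection_rule"]))
            if doc.get("selection_rule")
            else None
        )
        return cls(
            doc["pathway"],
            [(e[0], int(e[1]), e[2]) for e in doc["entries"]],
            rule,
        )


def select_snps(
    effects: pd.DataFrame, pathway: str, rule: SelectionRule | None = None
) -> GrsDefinition:
    """Select SNPs whose variant categories meet the pathway rule.

    A SNP is selected if ANY variant category satisfies the rule on the
    absolute proportional difference; its sign comes from the qualifying
    category with the largest |proportional difference|.  Conflicting
    qualifying signs within a SNP are resolved toward the larger
    magnitude with a logged warning.
    """
    if pathway not in DEFAULT_SELECTION_RULES and rule is None:
        raise ConfigurationError(f"no default selection rule for pathway {pathway!r}")
    rule = rule or DEFAULT_SELECTION_RULES[pathway]
    entries = []
    variant_rows = effects[effects["category"] != "common_hom"]
    for snp, grp in variant_rows.groupby("snp", sort=False):
        qual = grp[[rule.qualifies(r["prop_diff"], r["p"]) for _, r in grp.iterrows()]]
        if qual.empty:
            continue
        best = qual.loc[qual["prop_diff"].abs().idxmax()]
        signs = set(np.sign(qual["prop_diff"]))
        if len(signs) > 1:
            logger.warning(
                "%s: conflicting qualifying signs; using the larger-magnitude sign %+d",
                snp,
                int(best["sign"]),
            )
        entries.append((snp, int(best["sign"]), best["coding_mode"]))
    return GrsDefinition(pathway, entries, rule)


def compute_grs(
    genotypes: pd.DataFrame,
    definition: GrsDefinition,
    missing_policy: str = "zero",
    return_missing: bool = False,
):
    """Score participants: signed variant-allele points summed over SNPs.

    Dosage-coded SNPs contribute sign x dosage (0/1/2); carrier-coded
    SNPs contribute sign x carrier indicator.  Missing genotypes
    contribute 0 (``missing_policy='zero'``) or the SNP's mean
    contribution (``'mean'``); the per-participant count of missing
    score SNPs is returned when ``return_missing`` is set.
    """
    if len(definition) == 0:
        raise ConfigurationError("GRS definition is empty; no SNPs were selected")
    if missing_policy not in ("zero", "mean"):
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    absent = [snp for snp, _, _ in definition.entries if snp not in genotypes.columns]
    if absent:
        raise ConfigurationError(f"SNPs in definition absent from genotype table: {absent}")

    index = (
        genotypes["participant_id"]
        if "participant_id" in genotypes.columns
        else genotypes.index
    )
    score = pd.Series(0.0, index=index)
    n_missing = pd.Series(0, index=index)
    for snp, sign, mode in definition.entries:
        d = pd.Series(np.asarray(genotypes[snp], float), index=index)
        contrib = d if mode == "dosage" else (d > 0).astype(float).where(d.notna())
        if missing_policy == "mean":
            contrib = contrib.fillna(contrib.mean())
        else:
            contrib = contrib.fillna(0.0)
        n_missing += d.isna().astype(int)
        score += sign * contrib
    score.name = f"grs_{definition.pathway.lower()}"
    if missing_policy == "zero":
        score = score.astype(int) if float(score.round().sub(score).abs().max()) == 0 else score
    return (score, n_missing) if return_missing else score


class GrsScorer(BaseEstimator, TransformerMixin):
    """Oxidative-stress-specific genetic risk score, scikit-learn style.

    ``fit`` runs the full training sequence on a cohort — genotype QC
    (Hardy-Weinberg exact test, sparse-cell collapsing at
    ``collapse_threshold``), per-genotype sex- and BMI-adjusted
    geometric-mean FiP comparison, threshold selection — and stores the
    resulting score definition; ``transform`` scores any genotype table
    containing the selected SNPs.

    Parameters
    ----------
    pathway : {"AE", "BER"}
        Which pathway's default selection thresholds to use.
    selection_rule : SelectionRule, optional
        Override the default pathway rule.
    collapse_threshold : int, default 10
        Variant-genotype cell size at or below which carrier coding is used.
    missing_policy : {"zero", "mean"}, default "zero"
        Contribution of missing genotypes at scoring time.
    hwe_exclude_alpha : float, optional
        If set, SNPs with exact HWE p <= alpha are excluded from
        candidacy (off by default: HWE failure is reported, not acted on).

    Attributes
    ----------
    effects_ : DataFrame of per-genotype adjusted means and contrasts.
    definition_ : GrsDefinition with the selected signed SNPs.
    qc_ : DataFrame of per-SNP counts, MAF, HWE p and coding mode.
    """

    def __init__(
        self,
        pathway: str = "BER",
        selection_rule: SelectionRule | None = None,
        collapse_threshold: int = 10,
        missing_policy: str = "zero",
        hwe_exclude_alpha: float | None = None,
    ):
        self.pathway = pathway
        self.selection_rule = selection_rule
        self.collapse_threshold = collapse_threshold
        self.missing_policy = missing_policy
        self.hwe_exclude_alpha = hwe_exclude_alpha

    def fit(self, X: pd.DataFrame, y, sex=None, bmi=None, snp_meta: pd.DataFrame | None = None):
        """Learn the score definition from genotypes ``X`` and FiP ``y``."""
        X = pd.DataFrame(X)
        snp_cols = [c for c in X.columns if c != "participant_id"]
        if snp_meta is not None:
            wanted = set(snp_meta.loc[snp_meta["pathway"] == self.pathway, "rsid"])
            snp_cols = [c for c in snp_cols if c in wanted]
        if not snp_cols:
            raise ConfigurationError(f"no candidate SNPs for pathway {self.pathway!r}")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ConfigurationError("genotypes and FiP have different lengths")

        qc_rows, effect_frames = [], []
        for snp in snp_cols:
            counts = genotype_counts(X[snp])
            if counts.total == 0:
                warnings.warn(f"{snp}: no called genotypes; skipped")
                continue
            coding = collapse_sparse_genotypes(counts, self.collapse_threshold, snp)
            hwe_p = hwe_exact_test(counts)
            excluded = bool(
                self.hwe_exclude_alpha is not None and hwe_p <= self.hwe_exclude_alpha
            )
            qc_rows.append(
                {
                    "rsid": snp,
                    "n": counts.total,
                    "n_common_hom": counts.n_common_hom,
                    "n_het": counts.n_het,
                    "n_var_hom": counts.n_var_hom,
                    "hwe_p": hwe_p,
                    "coding_mode": coding.coding_mode,
                    "excluded": excluded,
                }
            )
            if excluded or (counts.n_het + counts.n_var_hom) == 0:
                continue
            effect_frames.append(
                adjusted_genotype_means(X[snp], y, sex=sex, bmi=bmi, coding=coding, snp_id=snp)
            )
        self.qc_ = pd.DataFrame(qc_rows)
        self.effects_ = (
            pd.concat(effect_frames, ignore_index=True)
            if effect_frames
            else pd.DataFrame(
                columns=["snp", "category", "coding_mode", "n", "adj_geometric_mean",
                         "ci_low", "ci_high", "prop_diff", "p", "sign"]
            )
        )
        self.definition_ = select_snps(self.effects_, self.pathway, self.selection_rule)
        logger.info(
            "%s GRS: %d of %d candidate SNPs selected",
            self.pathway,
            len(self.definition_),
            len(snp_cols),
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        """Score a genotype table with the fitted definition."""
        if not hasattr(self, "definition_"):
            raise ModelError("GrsScorer is not fitted")
        return compute_grs(pd.DataFrame(X), self.definition_, self.missing_policy)
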