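"""Ordered exclusion cascade with an audit trail.

Records are removed sequentially by a configurable, ordered list of
record-local rules; a record that violates several rules is attributed
to the FIRST rule in the configured order.  Because every rule looks at
one record at a time, reordering the rules changes only the attribution
of removals, never the final retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .simulate import CATEGORICAL_COMPONENTS

logger = logging.getLogger(__name__)


@dataclass
class ExclusionAudit:
    """Ordered record of the cascade: (rule, n removed, n remaining)."""

    steps: pd.DataFrame  # columns: rule, n_removed, n_remaining
    n_input: int

    @property
    def n_final(self) -> int:
        if len(self.steps) == 0:
            return self.n_input
        return int(self.steps["n_remaining"].iloc[-1])

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)


def _flag_missing_fip(p, g, meta, params):
    return p["fip"].isna()


def _flag_extreme_fip(p, g, meta, params):
    return p["fip"].notna() & (p["fip"] > params.get("fip_max", 380.0))


def _flag_genotype_missingness(p, g, meta, params):
    # a gene counts as missing when ALL of its SNPs are missing for the
    # participant; exclude when > threshold of panel genes are missing
    threshold = params.get("gene_fraction_max", 0.20)
    genes = meta.groupby("gene")["rsid"].apply(list)
    gt = g.set_index("participant_id")
    gene_missing = pd.DataFrame(
        {gene: gt[rsids].isna().all(axis=1) for gene, rsids in genes.items()}
    )
    frac = gene_missing.mean(axis=1)
    frac = frac.reindex(p["participant_id"]).fillna(1.0)
    return pd.Series(frac.values > threshold, index=p.index)


def _flag_non_white(p, g, meta, params):
    return p["race_white"].isna() | (p["race_white"] == False)  # noqa: E712


def _flag_missing_lifestyle(p, g, meta, params):
    cols = [c for c in CATEGORICAL_COMPONENTS if c in p.columns]
    mask = pd.Series(False, index=p.index)
    for c in cols:
        mask |= p[c].isna()
    return mask


def _flag_ffq_incomplete(p, g, meta, params):
    thr = params.get("ffq_fraction_max", 0.15)
    return p["ffq_missing_fraction"].notna() & (p["ffq_missing_fraction"] > thr)


def _flag_implausible_energy(p, g, meta, params):
    lo = params.get("energy_min", 600.0)
    hi = params.get("energy_max", 6000.0)
    e = p["total_energy"]
    return e.notna() & ((e < lo) | (e > hi))


def _flag_extreme_supplemental_carotene(p, g, meta, params):
    thr = params.get("carotene_max", 10000.0)
    c = p["supplemental_carotene"]
    return c.notna() & (c > thr)


_RULES = {
    "missing_fip": _flag_missing_fip,
    "extreme_fip": _flag_extreme_fip,
    "genotype_missingness": _flag_genotype_missingness,
    "non_white": _flag_non_white,
    "missing_lifestyle": _flag_missing_lifestyle,
    "ffq_incomplete": _flag_ffq_incomplete,
    "implausible_energy": _flag_implausible_energy,
    "extreme_supplemental_carotene": _flag_extreme_supplemental_carotene,
}

#: The default cascade: missing biomarker, extreme biomarker (>380 pg/mL),
#: gene-level genotype missingness (>20% of genes), non-White, missing
#: lifestyle data, incomplete FFQ (>15%), implausible energy intake
#: (<600 or >6,000 kcal/day), extreme supplemental carotene (>10,000 IU/day).
#: All thresholds are strict inequalities; boundary values are retained.
DEFAULT_RULES = tuple(_RULES)


def apply_exclusions(participants, genotypes, rules=DEFAULT_RULES, params=None):
    """Apply the ordered cascade; return filtered tables plus the audit.

    ``rules`` is an ordered sequence of rule names (see ``DEFAULT_RULES``);
    ``params`` optionally overrides rule thresholds.  ``genotypes`` may be
    ``(genotype_table, snp_meta)`` when the genotype-missingness rule is
    active; otherwise a bare genotype table (or None) is accepted.
    """
    params = params or {}
    if isinstance(genotypes, tuple):
        genotypes, snp_meta = genotypes
    else:
        snp_meta = None
    unknown = [r for r in rules if r not in _RULES]
    if unknown:
        raise ConfigurationError(f"unknown exclusion rule(s): {unknown}")
    if "genotype_missingness" in rules and (genotypes is None or snp_meta is None):
        raise ConfigurationError(
            "genotype_missingness rule requires (genotype table, snp_meta)"
        )

    n_input = len(participants)
    remaining = participants
    steps = []
    for rule in rules:
        flag = _RULES[rule](remaining, genotypes, snp_meta, params)
        n_removed = int(flag.sum())
        remaining = remaining.loc[~flag]
        steps.append((rule, n_removed, len(remaining)))
        if n_removed:
            logger.info("exclusion %-30s removed %4d, remaining %4d", rule, n_removed, len(remaining))
    audit = ExclusionAudit(
        pd.DataFrame(steps, columns=["rule", "n_removed", "n_remaining"]), n_input
    )
    kept = set(remaining["participant_id"])
    genotypes_out = (
        genotypes.loc[genotypes["participant_id"].isin(kept)].reset_index(drop=True)
        if genotypes is not None
        else None
    )
    return remaining.reset_index(drop=True), genotypes_out, audit
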