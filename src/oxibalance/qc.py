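"""Genotype quality control: exact Hardy-Weinberg tests and sparse-cell collapsing.

The Hardy-Weinberg test is the conditional exact test: given the
observed allele counts, the number of heterozygotes follows a known
discrete distribution under equilibrium, and the two-sided p-value sums
the probabilities of all heterozygote counts no more probable than the
observed one.  Probabilities are computed by the standard stable
recurrence across neighbouring heterozygote counts.  A chi-square
variant is provided for comparison, but the exact test is the default
because collapsing is triggered precisely when genotype cells are
sparse — the regime where the asymptotic test is least trustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError

#: Relative tie tolerance: heterozygote counts whose probability is within
#: this factor above the observed one still count as "as extreme", so exact
#: symmetric ties are never split by floating-point rounding.
_TIE_REL_TOL = 1e-9


@dataclass(frozen=True)
class GenotypeCountTriple:
    n_common_hom: int
    n_het: int
    n_var_hom: int

    @property
    def total(self) -> int:
        return self.n_common_hom + self.n_het + self.n_var_hom


@dataclass(frozen=True)
class GenotypeCoding:
    """How a SNP enters downstream models.

    ``dosage`` keeps the three genotype categories; ``carrier`` merges
    variant-allele heterozygotes and homozygotes into one carrier
    category (applied when either variant-containing cell is sparse).
    """

    snp_id: str
    categories: tuple
    coding_mode: str  # "dosage" | "carrier"


def _as_triple(counts) -> tuple:
    if isinstance(counts, GenotypeCountTriple):
        t = (counts.n_common_hom, counts.n_het, counts.n_var_hom)
    else:
        t = tuple(int(c) for c in counts)
    if len(t) != 3:
        raise ConfigurationError("genotype counts must be a (common_hom, het, var_hom) triple")
    if any(c < 0 for c in t):
        raise ConfigurationError(f"genotype counts must be non-negative, got {t}")
    return t


def _het_distribution(n_genotypes: int, n_minor: int):
    """Probabilities of each possible heterozygote count given allele totals.

    Returns (heterozygote counts, probabilities).  Uses the ratio
    recurrence between adjacent counts, anchored at the mid-range count,
    then normalizes — each term keeps full relative accuracy even deep
    in the tails.
    """
    h_min = n_minor % 2
    h_max = min(n_minor, 2 * n_genotypes - n_minor)
    hets = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(len(hets), dtype=float)
    # anchor near the distribution mode (expected het under HWE)
    h0 = int(round(n_minor * (2 * n_genotypes - n_minor) / (2.0 * n_genotypes)))
    h0 = min(max(h0, h_min), h_max)
    if (h0 - h_min) % 2:
        h0 -= 1 if h0 > h_min else -1
    i0 = (h0 - h_min) // 2
    probs[i0] = 1.0
    for i in range(i0, 0, -1):  # downward: h -> h - 2
        h = hets[i]
        hom_r = (n_minor - h) // 2
        hom_c = n_genotypes - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for i in range(i0, len(hets) - 1):  # upward: h -> h + 2
        h = hets[i]
        hom_r = (n_minor - h) // 2
        hom_c = n_genotypes - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 1.0) * (h + 2.0))
    probs /= probs.sum()
    return hets, probs


def hwe_exact_pvalues_all(n_genotypes: int, n_minor: int):
    """Exact HWE p-value for every possible heterozygote count.

    Returns (heterozygote counts, p-values), with the p-value for each
    count defined as the total probability of all counts at most as
    probable (two-sided, conditional on allele totals).
    """
    hets, probs = _het_distribution(n_genotypes, n_minor)
    order = np.argsort(probs, kind="stable")
    csum = np.cumsum(probs[order])
    # for each het, total mass of counts with prob <= prob_h * (1 + tol)
    idx = np.searchsorted(probs[order], probs * (1.0 + _TIE_REL_TOL), side="right")
    pvals = np.minimum(csum[idx - 1], 1.0)
    return hets, pvals


def hwe_exact_test(counts) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one SNP.

    ``counts`` is (n_common_hom, n_het, n_var_hom).  Monomorphic SNPs
    return 1.  The test is symmetric in which allele is called minor.
    """
    a, h, b = _as_triple(counts)
    n = a + h + b
    if n < 1:
        raise ConfigurationError("total genotype count must be >= 1")
    n_minor = min(2 * a + h, 2 * b + h)
    if n_minor == 0:
        return 1.0
    hets, pvals = hwe_exact_pvalues_all(n, n_minor)
    return float(pvals[np.searchsorted(hets, h)])


def hwe_chisq_test(counts) -> float:
    """One-degree-of-freedom chi-square HWE test (asymptotic comparator)."""
    a, h, b = _as_triple(counts)
    n = a + h + b
    if n < 1:
        raise ConfigurationError("total genotype count must be >= 1")
    p = (2 * a + h) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    chi2 = float(np.sum((np.array([a, h, b]) - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def collapse_sparse_genotypes(counts, threshold: int = 10, snp_id: str = "") -> GenotypeCoding:
    """Merge variant-allele genotypes into a carrier category when sparse.

    If the heterozygote OR the variant-homozygote cell holds at most
    ``threshold`` participants, the two variant-containing categories are
    combined into one carrier category; the common homozygote is never
    merged.
    """
    _, h, b = _as_triple(counts)
    if h <= threshold or b <= threshold:
        return GenotypeCoding(snp_id, ("common_hom", "carrier"), "carrier")
    return GenotypeCoding(snp_id, ("common_hom", "het", "var_hom"), "dosage")


def genotype_counts(dosages) -> GenotypeCountTriple:
    """Count genotype categories from a dosage vector (NaN = missing)."""
    d = pd.Series(dosages).dropna()
    return GenotypeCountTriple(
        int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
    )


def qc_report(
    genotypes: pd.DataFrame,
    snp_meta: pd.DataFrame,
    collapse_threshold: int = 10,
    hwe_exclude_alpha: float | None = None,
) -> pd.DataFrame:
    """Per-SNP QC table: counts, MAF, HWE p, coding mode.

    HWE failure is reported, not acted on, unless ``hwe_exclude_alpha``
    is given, in which case SNPs with p <= alpha are flagged
    ``excluded=True`` for downstream stages to drop.
    """
    rows = []
    for _, snp in snp_meta.iterrows():
        rsid = snp["rsid"]
        counts = genotype_counts(genotypes[rsid])
        n = counts.total
        maf = (
            min(2 * counts.n_common_hom + counts.n_het, 2 * counts.n_var_hom + counts.n_het)
            / (2.0 * n)
            if n
            else np.nan
        )
        p = hwe_exact_test(counts) if n else np.nan
        coding = collapse_sparse_genotypes(counts, collapse_threshold, rsid)
        rows.append(
            {
                "rsid": rsid,
                "gene": snp["gene"],
                "pathway": snp["pathway"],
                "n": n,
                "n_common_hom": counts.n_common_hom,
                "n_het": counts.n_het,
                "n_var_hom": counts.n_var_hom,
                "maf": maf,
                "hwe_p": p,
                "coding_mode": coding.coding_mode,
                "excluded": bool(
                    hwe_exclude_alpha is not None and p is not None and p <= hwe_exclude_alpha
                ),
            }
        )
    return pd.DataFrame(rows)
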