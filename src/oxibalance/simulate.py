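"""Synthetic pooled-cohort generator with planted, recoverable effects.

Emulates a pooled pair of cross-sectional colonoscopy-screening studies
("MAP I"/"MAP II"): plasma F2-isoprostane (FiP) concentrations on a
log-normal scale, SNP genotypes in Hardy-Weinberg equilibrium at
configurable minor-allele frequencies with multiplicative planted
effects on the FiP geometric mean, and 17 anti-/pro-oxidant diet and
lifestyle exposure components with planted log-linear effects.  Every
planted quantity is carried along in a truth table so downstream
estimation stages can be validated against a known ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import ConfigurationError

logger = logging.getLogger(__name__)

STUDIES = ("MAP1", "MAP2")
SEXES = ("male", "female")
EDUCATION_LEVELS = ("lt_high_school", "high_school", "college_plus")

#: Continuous OBS components (intakes per 1,000 kcal/day), antioxidant then
#: pro-oxidant.  Categorical lifestyle components follow.
CONTINUOUS_COMPONENTS = (
    "vitamin_c",
    "vitamin_e",
    "carotene",
    "lutein",
    "lycopene",
    "flavonoids",
    "glucosinolates",
    "omega3",
    "selenium",
    "calcium",
    "iron",
    "omega6",
    "saturated_fat",
)
CATEGORICAL_COMPONENTS = ("alcohol", "bmi_category", "smoking", "physical_activity")
ALL_COMPONENTS = CONTINUOUS_COMPONENTS + CATEGORICAL_COMPONENTS


@dataclass(frozen=True)
class SnpSpec:
    """One SNP in the genotyping panel.

    ``maf`` is the variant (minor) allele frequency; genotypes are drawn
    as Binomial(2, maf), i.e. Hardy-Weinberg proportions.
    """

    rsid: str
    gene: str
    pathway: str  # "AE" or "BER"
    maf: float


@dataclass(frozen=True)
class ContinuousComponent:
    """A continuous exposure component.

    ``mean``/``sd`` may be scalars or ``{(study, sex): value}`` mappings
    for stratum-specific distributions.  ``beta`` is the planted change in
    natural-log FiP per 1 SD of the component (0.0 = null).
    """

    mean: float | dict = 0.0
    sd: float | dict = 1.0
    beta: float = 0.0

    def stratum_mean(self, study: str, sex: str) -> float:
        return self.mean[(study, sex)] if isinstance(self.mean, dict) else self.mean

    def stratum_sd(self, study: str, sex: str) -> float:
        return self.sd[(study, sex)] if isinstance(self.sd, dict) else self.sd


@dataclass(frozen=True)
class CategoricalComponent:
    """A categorical lifestyle component.

    ``betas`` are planted changes in natural-log FiP for each level
    relative to the first (referent) level, which must carry 0.
    """

    levels: tuple
    probs: tuple
    betas: tuple = None

    def __post_init__(self):
        if self.betas is None:
            object.__setattr__(self, "betas", tuple(0.0 for _ in self.levels))


def _default_continuous() -> dict:
    # Means/SDs loosely follow the pooled-study dietary intake table
    # (units per 1,000 kcal/day); scale is immaterial downstream because
    # components are re-standardized within study-sex strata.
    vals = {
        "vitamin_c": (55.0, 136.0),
        "vitamin_e": (37.0, 78.0),
        "carotene": (4440.0, 3590.0),
        "lutein": (1634.0, 1274.0),
        "lycopene": (2768.0, 2508.0),
        "flavonoids": (258.0, 256.0),
        "glucosinolates": (10.6, 10.9),
        "omega3": (0.117, 0.097),
        "selenium": (4.6, 15.4),
        "calcium": (494.0, 322.0),
        "iron": (12.2, 13.5),
        "omega6": (6.4, 2.3),
        "saturated_fat": (11.6, 2.9),
    }
    return {
        name: ContinuousComponent(mean=m, sd=s, beta=0.0) for name, (m, s) in vals.items()
    }


def _default_categorical() -> dict:
    return {
        "alcohol": CategoricalComponent(("none", "moderate", "heavy"), (0.30, 0.61, 0.09)),
        "bmi_category": CategoricalComponent(
            ("normal", "overweight", "obese"), (0.35, 0.40, 0.25)
        ),
        "smoking": CategoricalComponent(("never", "former", "current"), (0.45, 0.41, 0.14)),
        "physical_activity": CategoricalComponent(
            ("low", "moderate", "high"), (1 / 3, 1 / 3, 1 / 3)
        ),
    }


def default_snp_panel() -> list:
    """A synthetic stand-in genotyping panel.

    Covers the two pathways with plausible gene symbols (antioxidant
    enzymes: GSTP1, CAT, MnSOD; base excision repair: XRCC1, TDG, PNKP,
    MUTYH, FEN1) and common-variant MAFs; the rsIDs are synthetic labels,
    not real dbSNP identifiers.
    """
    ae = [
        ("snpAE01", "GSTP1", 0.32),
        ("snpAE02", "GSTP1", 0.28),
        ("snpAE03", "GSTP1", 0.11),
        ("snpAE04", "CAT", 0.22),
        ("snpAE05", "CAT", 0.41),
        ("snpAE06", "MnSOD", 0.47),
    ]
    ber = [
        ("snpBER01", "XRCC1", 0.35),
        ("snpBER02", "XRCC1", 0.12),
        ("snpBER03", "TDG", 0.08),
        ("snpBER04", "TDG", 0.27),
        ("snpBER05", "PNKP", 0.17),
        ("snpBER06", "PNKP", 0.36),
        ("snpBER07", "MUTYH", 0.30),
        ("snpBER08", "MUTYH", 0.05),
        ("snpBER09", "FEN1", 0.33),
        ("snpBER10", "OGG1", 0.21),
    ]
    return [SnpSpec(r, g, "AE", m) for r, g, m in ae] + [
        SnpSpec(r, g, "BER", m) for r, g, m in ber
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic cohort.

    Planted SNP effects are multiplicative on the FiP geometric mean per
    variant allele (1.0 = null); exposure betas are additive on
    natural-log FiP.  ``seed`` makes the draw bit-reproducible.
    """

    n_participants: int = 245
    snp_panel: tuple = field(default_factory=lambda: tuple(default_snp_panel()))
    planted_snp_effects: dict = field(default_factory=dict)
    continuous_components: dict = field(default_factory=_default_continuous)
    categorical_components: dict = field(default_factory=_default_categorical)
    component_correlation: float = 0.0
    sex_ratio: float = 0.457  # fraction male
    study_ratio: float = 151 / 245  # fraction MAP1
    baseline_log_fip: float = math.log(80.0)
    noise_sd: float = 0.35
    missing_genotype_rate: float = 0.02
    hrt_prob_women: float = 0.56
    seed: int = 0

    def __post_init__(self):
        for snp in self.snp_panel:
            if not (0.0 < snp.maf <= 0.5):
                raise ConfigurationError(
                    f"snp_panel: MAF for {snp.rsid} must be in (0, 0.5], got {snp.maf}"
                )
        unknown = set(self.planted_snp_effects) - {s.rsid for s in self.snp_panel}
        if unknown:
            raise ConfigurationError(
                f"planted_snp_effects: rsIDs not in snp_panel: {sorted(unknown)}"
            )
        for rsid, eff in self.planted_snp_effects.items():
            if eff <= 0:
                raise ConfigurationError(
                    f"planted_snp_effects: effect for {rsid} must be > 0, got {eff}"
                )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0.0 <= self.missing_genotype_rate < 1.0):
            raise ConfigurationError(
                f"missing_genotype_rate must be in [0, 1), got {self.missing_genotype_rate}"
            )
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ConfigurationError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        if not (0.0 <= self.study_ratio <= 1.0):
            raise ConfigurationError(f"study_ratio must be in [0, 1], got {self.study_ratio}")
        if not (-1.0 / max(1, len(self.continuous_components) - 1) < self.component_correlation < 1.0):
            raise ConfigurationError(
                f"component_correlation must give a valid covariance, got {self.component_correlation}"
            )
        for name, comp in self.categorical_components.items():
            if len(comp.levels) != len(comp.probs) or len(comp.levels) != len(comp.betas):
                raise ConfigurationError(
                    f"categorical_components[{name}]: levels/probs/betas length mismatch"
                )
            if abs(sum(comp.probs) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"categorical_components[{name}]: probabilities sum to "
                    f"{sum(comp.probs)}, expected 1"
                )
            if comp.betas[0] != 0.0:
                raise ConfigurationError(
                    f"categorical_components[{name}]: referent level beta must be 0"
                )

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its generative ground truth."""

    participants: pd.DataFrame
    genotypes: pd.DataFrame  # participant_id + one float column per rsID (NaN = missing)
    snp_meta: pd.DataFrame  # rsid, gene, pathway, maf
    expected_log_fip: pd.Series  # linear predictor, noise excluded
    config: SimulationConfig


def default_map_config(**overrides) -> SimulationConfig:
    """The default pooled-study conditions (n=245, null effects)."""
    return SimulationConfig(**overrides)


# BMI distribution within each reported category, kg/m^2 (mean, sd, lo, hi)
_BMI_BANDS = {
    "normal": (22.5, 1.8, 17.0, 24.9),
    "overweight": (27.3, 1.4, 25.0, 29.9),
    "obese": (33.5, 3.5, 30.0, 55.0),
}


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort from the configured generative model.

    Genotypes: Binomial(2, MAF) per SNP (Hardy-Weinberg).  Natural-log
    FiP = baseline + sum(dosage x ln effect) + sum(exposure betas) +
    Normal(0, noise_sd); FiP is reported on the pg/mL scale.  Missing
    genotypes are inserted completely at random at the configured rate
    (after the phenotype is generated, mimicking assay failure).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    study = np.where(rng.random(n) < config.study_ratio, "MAP1", "MAP2")
    sex = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    age = np.clip(rng.normal(57.2, 8.6, n), 30.0, 74.0).round(1)

    # genotypes (true dosages, HWE) and their multiplicative FiP effects
    dosages = {}
    log_fip = np.full(n, config.baseline_log_fip)
    for snp in config.snp_panel:
        d = rng.binomial(2, snp.maf, n)
        dosages[snp.rsid] = d
        effect = config.planted_snp_effects.get(snp.rsid, 1.0)
        if effect != 1.0:
            log_fip = log_fip + d * math.log(effect)

    # continuous exposure components: correlated standard-normal scores,
    # mapped to raw scale within study-sex strata
    cont_names = list(config.continuous_components)
    k = len(cont_names)
    if k:
        rho = config.component_correlation
        cov = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        raw = np.empty_like(z)
        for j, name in enumerate(cont_names):
            comp = config.continuous_components[name]
            for st in STUDIES:
                for sx in SEXES:
                    m = (study == st) & (sex == sx)
                    raw[m, j] = comp.stratum_mean(st, sx) + comp.stratum_sd(st, sx) * z[m, j]
            if comp.beta:
                log_fip = log_fip + comp.beta * z[:, j]
    else:
        raw = np.empty((n, 0))

    cat_draws = {}
    for name, comp in config.categorical_components.items():
        idx = rng.choice(len(comp.levels), size=n, p=np.asarray(comp.probs, float))
        cat_draws[name] = np.asarray(comp.levels, object)[idx]
        betas = np.asarray(comp.betas, float)
        if betas.any():
            log_fip = log_fip + betas[idx]

    expected_log_fip = pd.Series(log_fip.copy(), index=ids, name="expected_log_fip")
    if config.noise_sd > 0:
        log_fip = log_fip + rng.normal(0.0, config.noise_sd, n)
    fip = np.exp(log_fip)

    # continuous BMI consistent with the drawn BMI category
    bmi = np.empty(n)
    if "bmi_category" in cat_draws:
        for level, (m_, s_, lo, hi) in _BMI_BANDS.items():
            mask = cat_draws["bmi_category"] == level
            bmi[mask] = np.clip(rng.normal(m_, s_, mask.sum()), lo, hi)
    else:
        bmi = np.clip(rng.normal(27.9, 6.0, n), 17.0, 55.0)
    bmi = bmi.round(1)

    hrt = np.where(
        sex == "female", rng.random(n) < config.hrt_prob_women, False
    )  # men are never HRT users

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "study": study,
            "sex": sex,
            "age": age,
            "fip": fip,
            "bmi": bmi,
            "total_energy": np.clip(rng.normal(1860.0, 720.0, n), 300.0, 8000.0).round(0),
            "education": rng.choice(EDUCATION_LEVELS, size=n, p=[0.15, 0.56, 0.29]),
            "hrt_current": hrt,
            "nsaid_regular": rng.random(n) < 0.28,
            "ffq_missing_fraction": rng.beta(1.0, 40.0, n).round(4),
            "supplemental_carotene": np.exp(rng.normal(6.5, 1.5, n)).round(0),
            "race_white": rng.random(n) < 0.995,
        }
    )
    for j, name in enumerate(cont_names):
        participants[name] = raw[:, j]
    for name, values in cat_draws.items():
        participants[name] = values

    geno_cols = {"participant_id": ids}
    for snp in config.snp_panel:
        col = dosages[snp.rsid].astype(float)
        if config.missing_genotype_rate > 0:
            col[rng.random(n) < config.missing_genotype_rate] = np.nan
        geno_cols[snp.rsid] = col
    genotypes = pd.DataFrame(geno_cols)

    snp_meta = pd.DataFrame(
        [(s.rsid, s.gene, s.pathway, s.maf) for s in config.snp_panel],
        columns=["rsid", "gene", "pathway", "maf"],
    )
    logger.info(
        "simulated cohort: n=%d, %d SNPs, seed=%d", n, len(config.snp_panel), config.seed
    )
    return SyntheticCohort(participants, genotypes, snp_meta, expected_log_fip, config)


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Tabulate every planted effect for joining against estimates.

    One row per SNP (multiplicative effect on the FiP geometric mean per
    variant allele) and per exposure component (additive effect on ln
    FiP); null effects are included so the table always has one row per
    panel SNP plus one per component level carrying an effect slot.
    """
    cfg = cohort.config
    rows = []
    for snp in cfg.snp_panel:
        rows.append(
            {
                "kind": "snp",
                "name": snp.rsid,
                "level": "per_allele",
                "multiplicative_effect": cfg.planted_snp_effects.get(snp.rsid, 1.0),
                "log_beta": math.log(cfg.planted_snp_effects.get(snp.rsid, 1.0)),
            }
        )
    for name, comp in cfg.continuous_components.items():
        rows.append(
            {
                "kind": "continuous_component",
                "name": name,
                "level": "per_sd",
                "multiplicative_effect": math.exp(comp.beta),
                "log_beta": comp.beta,
            }
        )
    for name, comp in cfg.categorical_components.items():
        for level, beta in zip(comp.levels[1:], comp.betas[1:]):
            rows.append(
                {
                    "kind": "categorical_component",
                    "name": name,
                    "level": level,
                    "multiplicative_effect": math.exp(beta),
                    "log_beta": beta,
                }
            )
    return pd.DataFrame(rows)
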