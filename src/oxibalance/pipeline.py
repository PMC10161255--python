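"""Pipeline orchestration, recovery experiments and worked-arithmetic checks.

``run_pipeline`` executes the full sequence — exclusions, genotype QC,
GRS construction for both pathways, OBS construction, and the
category/stratified/joint association analyses — writing every stage
output as CSV plus a manifest; identical config and seed give
byte-identical outputs.  ``recovery_experiment`` repeats
simulate-then-analyze cycles over a grid of planted effects and
aggregates selection sensitivity/specificity, sign accuracy and CI
coverage, with binomial Monte-Carlo standard errors attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, OxibalanceError
from .association import CategorySpec, adjusted_means_by_category, assign_categories, joint_grs_analysis, stratified_association
from .exclusions import DEFAULT_RULES, apply_exclusions
from .grs import GrsScorer
from .io import write_cohort
from .obs import ObsScorer
from .qc import qc_report
from .simulate import (
    ContinuousComponent,
    SimulationConfig,
    SyntheticCohort,
    simulate_cohort,
    truth_report,
)

logger = logging.getLogger(__name__)

#: Removal counts of the pooled-study exclusion cascade, in rule order
#: (missing FiP; FiP > 380 pg/mL; gene-level genotype missingness > 20%;
#: non-White; missing lifestyle; FFQ > 15% missing; energy < 600 or
#: > 6,000 kcal/day; supplemental carotene > 10,000 IU/day).
MAP_EXCLUSION_REMOVALS = (292, 2, 184, 30, 12, 10, 10, 8)
MAP_FINAL_N = 245


def build_flagged_roster(removals=MAP_EXCLUSION_REMOVALS, n_clean=MAP_FINAL_N, seed=0):
    """Synthetic roster engineered so each cascade rule removes a set count.

    Builds ``sum(removals) + n_clean`` records from a clean simulated
    template, then corrupts disjoint blocks so that block *k* violates
    exactly rule *k* (and no earlier rule).  Returns (participants,
    genotypes, snp_meta).
    """
    n = int(sum(removals)) + int(n_clean)
    cfg = SimulationConfig(n_participants=n, missing_genotype_rate=0.0, seed=seed)
    cohort = simulate_cohort(cfg)
    p = cohort.participants.copy()
    g = cohort.genotypes.copy()
    # scrub any incidental rule violations so the blocks are exact
    p["race_white"] = True
    p["ffq_missing_fraction"] = p["ffq_missing_fraction"].clip(upper=0.10)
    p["total_energy"] = p["total_energy"].clip(600.0, 6000.0)
    p["supplemental_carotene"] = p["supplemental_carotene"].clip(upper=9000.0)
    p["fip"] = p["fip"].clip(upper=350.0)

    start = 0
    blocks = []
    for r in removals:
        blocks.append(slice(start, start + r))
        start += r
    snp_cols = [c for c in g.columns if c != "participant_id"]
    p.loc[p.index[blocks[0]], "fip"] = np.nan
    p.loc[p.index[blocks[1]], "fip"] = 450.0
    g.loc[g.index[blocks[2]], snp_cols] = np.nan
    p.loc[p.index[blocks[3]], "race_white"] = False
    p.loc[p.index[blocks[4]], "smoking"] = np.nan
    p.loc[p.index[blocks[5]], "ffq_missing_fraction"] = 0.30
    p.loc[p.index[blocks[6]], "total_energy"] = 400.0
    p.loc[p.index[blocks[7]], "supplemental_carotene"] = 20000.0
    return p, g, cohort.snp_meta


def demo_config(seed: int = 0, n: int = 800) -> SimulationConfig:
    """A demonstration scenario with planted genetic and exposure effects.

    Two SNPs per pathway carry multiplicative FiP effects (1.30 and
    0.80 per variant allele); vitamin C and saturated fat carry
    log-linear exposure effects of -0.08 and +0.06 per SD.  A larger n
    than the pooled analytic sample is drawn so the cascade leaves a
    cohort of comparable size.
    """
    base = SimulationConfig(n_participants=n, seed=seed)
    cont = dict(base.continuous_components)
    cont["vitamin_c"] = ContinuousComponent(
        cont["vitamin_c"].mean, cont["vitamin_c"].sd, beta=-0.08
    )
    cont["saturated_fat"] = ContinuousComponent(
        cont["saturated_fat"].mean, cont["saturated_fat"].sd, beta=0.06
    )
    return base.with_(
        planted_snp_effects={
            "snpAE01": 1.30,
            "snpAE05": 0.80,
            "snpBER01": 1.30,
            "snpBER06": 0.80,
        },
        continuous_components=cont,
    )


def _dichotomy_cutpoint(scores: pd.Series) -> int:
    """Default integer cutpoint: ceil of the median (low < c <= high)."""
    c = int(np.ceil(np.median(scores)))
    if (scores >= c).all() or (scores < c).all():
        c = int(np.ceil(np.mean(scores)))
    if (scores >= c).all():
        c += 1
    return c


def run_pipeline(
    config: SimulationConfig | None = None,
    outdir="pipeline_output",
    cohort: SyntheticCohort | None = None,
    rules=DEFAULT_RULES,
    ae_cutpoint: int | None = None,
    ber_cutpoint: int | None = None,
) -> dict:
    """Run every stage in order and write all outputs plus a manifest.

    Either a ``SimulationConfig`` (a cohort is simulated) or an existing
    ``SyntheticCohort`` must be given.  Stages: exclusion cascade ->
    genotype QC -> AE and BER GRS construction -> OBS construction ->
    association analyses (GRS categories, OBS tertiles, stratified,
    joint).  Any stage error is re-raised with the stage named.
    Returns a result dict including the manifest.
    """
    if cohort is None:
        if config is None:
            raise ConfigurationError("run_pipeline needs a config or a cohort")
        cohort = simulate_cohort(config)
    config = cohort.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    results = {"config": config}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise OxibalanceError(f"stage {name!r} failed: {exc}") from exc

    outputs.update(_stage("write_inputs", lambda: write_cohort(cohort, outdir / "inputs")))
    outputs["truth_effects"] = str(outdir / "truth_effects.csv")
    truth_report(cohort).to_csv(outputs["truth_effects"], index=False)

    def _exclusions():
        return apply_exclusions(
            cohort.participants, (cohort.genotypes, cohort.snp_meta), rules=rules
        )

    participants, genotypes, audit = _stage("exclusions", _exclusions)
    if len(participants) == 0:
        raise OxibalanceError("stage 'exclusions' removed every participant")
    outputs["exclusion_audit"] = str(outdir / "exclusion_audit.csv")
    audit.to_csv(outputs["exclusion_audit"])
    results["audit"] = audit

    qc = _stage("genotype_qc", lambda: qc_report(genotypes, cohort.snp_meta))
    outputs["qc_report"] = str(outdir / "qc_report.csv")
    qc.to_csv(outputs["qc_report"], index=False)
    results["qc"] = qc

    if len(cohort.snp_meta) == 0:
        raise OxibalanceError("stage 'grs_construction' failed: empty SNP panel")

    scores = {}
    for pathway in ("AE", "BER"):
        def _fit(pathway=pathway):
            scorer = GrsScorer(pathway=pathway)
            scorer.fit(
                genotypes,
                participants["fip"].to_numpy(),
                sex=participants["sex"].to_numpy(),
                bmi=participants["bmi"].to_numpy(),
                snp_meta=cohort.snp_meta,
            )
            return scorer

        scorer = _stage(f"grs_construction[{pathway}]", _fit)
        key = pathway.lower()
        outputs[f"grs_{key}_effects"] = str(outdir / f"grs_{key}_effects.csv")
        scorer.effects_.to_csv(outputs[f"grs_{key}_effects"], index=False)
        outputs[f"grs_{key}_definition"] = str(outdir / f"grs_{key}_definition.yaml")
        scorer.definition_.save(outputs[f"grs_{key}_definition"])
        if len(scorer.definition_) == 0:
            raise OxibalanceError(
                f"stage 'grs_construction[{pathway}]' failed: no SNPs met the "
                f"selection rule; cannot score this cohort"
            )
        s = scorer.transform(genotypes)
        s.index = participants["participant_id"]
        scores[pathway] = s
        results[f"grs_{key}"] = scorer
        outputs[f"grs_{key}_scores"] = str(outdir / f"grs_{key}_scores.csv")
        s.rename_axis("participant_id").to_csv(outputs[f"grs_{key}_scores"])

    def _obs():
        scorer = ObsScorer()
        scorer.fit(participants, participants["fip"].to_numpy())
        return scorer

    obs_scorer = _stage("obs_construction", _obs)
    obs = obs_scorer.transform(participants)
    obs.index = participants["participant_id"]
    results["obs"] = obs_scorer
    outputs["obs_weights"] = str(outdir / "obs_weights.csv")
    obs_scorer.weights_.weights.to_csv(outputs["obs_weights"], index=False)
    outputs["obs_scores"] = str(outdir / "obs_scores.csv")
    obs.rename_axis("participant_id").to_csv(outputs["obs_scores"])

    # association stages: complete-case on the OBS and covariates
    analytic = participants.set_index("participant_id").copy()
    analytic["obs"] = obs
    analytic["grs_ae"] = scores["AE"]
    analytic["grs_ber"] = scores["BER"]
    analytic = analytic[analytic["obs"].notna()]
    ln_fip_cov = analytic[["sex"]].assign(obs=analytic["obs"])
    obs_cov = analytic[["total_energy", "sex", "hrt_current", "education", "nsaid_regular"]]

    def _associate():
        out = {}
        ber_labels, ber_med = assign_categories(analytic["grs_ber"], CategorySpec("tertile"))
        out["ber_tertiles"] = adjusted_means_by_category(
            analytic["fip"].values, ber_labels.values, ln_fip_cov, score_medians=ber_med
        )
        ae_cut = ae_cutpoint if ae_cutpoint is not None else _dichotomy_cutpoint(analytic["grs_ae"])
        ber_cut = ber_cutpoint if ber_cutpoint is not None else _dichotomy_cutpoint(analytic["grs_ber"])
        out["cutpoints"] = {"AE": ae_cut, "BER": ber_cut}
        ae_di, ae_med = assign_categories(
            analytic["grs_ae"], CategorySpec("dichotomy", ae_cut)
        )
        out["ae_dichotomy"] = adjusted_means_by_category(
            analytic["fip"].values, ae_di.values, ln_fip_cov, score_medians=ae_med
        )
        obs_labels, obs_med = assign_categories(analytic["obs"], CategorySpec("tertile"))
        out["obs_tertiles"] = adjusted_means_by_category(
            analytic["fip"].values, obs_labels.values, obs_cov, score_medians=obs_med
        )
        ber_di, _ = assign_categories(analytic["grs_ber"], CategorySpec("dichotomy", ber_cut))
        for pathway, di in (("AE", ae_di), ("BER", ber_di)):
            med_by_stratum = {
                lvl: analytic["obs"][ (di == lvl).values ]
                .groupby(obs_labels[(di == lvl).values])
                .median()
                .to_dict()
                for lvl in sorted(di.unique())
            }
            out[f"obs_by_{pathway.lower()}_stratum"] = stratified_association(
                analytic["fip"].values,
                obs_labels.values,
                di.values,
                covariates=obs_cov.reset_index(drop=True),
                obs_score_medians_by_stratum=med_by_stratum,
            )
        out["joint"] = joint_grs_analysis(
            analytic["fip"].values, ae_di.values, ber_di.values, ln_fip_cov.reset_index(drop=True)
        )
        return out

    assoc = _stage("association_analysis", _associate)
    results["associations"] = assoc
    for key in ("ber_tertiles", "ae_dichotomy", "obs_tertiles", "joint"):
        outputs[f"assoc_{key}"] = str(outdir / f"assoc_{key}.csv")
        assoc[key].to_csv(outputs[f"assoc_{key}"], index=False)
    for pathway in ("ae", "ber"):
        res = assoc[f"obs_by_{pathway}_stratum"]
        for lvl, tab in res["strata"].items():
            outputs[f"assoc_obs_by_{pathway}_{lvl}"] = str(
                outdir / f"assoc_obs_by_{pathway}_stratum{lvl}.csv"
            )
            tab.to_csv(outputs[f"assoc_obs_by_{pathway}_{lvl}"], index=False)
    interactions = pd.DataFrame(
        [
            {
                "pathway": pw.upper(),
                "p_interaction": assoc[f"obs_by_{pw}_stratum"]["p_interaction"],
                "p_interaction_dummy": assoc[f"obs_by_{pw}_stratum"]["p_interaction_dummy"],
            }
            for pw in ("ae", "ber")
        ]
    )
    outputs["interactions"] = str(outdir / "interactions.csv")
    interactions.to_csv(outputs["interactions"], index=False)

    from . import __version__

    config_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash,
        "n_input": int(audit.n_input),
        "n_analytic": int(len(participants)),
        # paths relative to outdir so reruns are byte-identical
        "outputs": sorted(
            str(Path(v).relative_to(outdir)) for v in outputs.values()
        ),
    }
    outputs["manifest"] = str(outdir / "manifest.json")
    with open(outputs["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    results["outputs"] = outputs
    logger.info("pipeline complete: %d outputs under %s", len(outputs), outdir)
    return results


# ---------------------------------------------------------------------------
# recovery experiments


def _selection_config(effect, maf, noise_sd, n, pathway, seed):
    from .simulate import SnpSpec

    panel = (SnpSpec("snpX", "GENEX", pathway, maf),)
    return SimulationConfig(
        n_participants=n,
        snp_panel=panel,
        planted_snp_effects={"snpX": effect} if effect != 1.0 else {},
        continuous_components={},
        categorical_components={},
        noise_sd=noise_sd,
        missing_genotype_rate=0.0,
        seed=seed,
    )


def snp_selection_experiment(
    effect: float,
    maf: float,
    noise_sd: float,
    n: int,
    n_replicates: int,
    pathway: str = "BER",
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated simulate-select cycles for one SNP scenario.

    Returns one row per replicate with ``selected`` and ``sign``
    (the sign assigned when selected, 0 otherwise).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cfg = _selection_config(effect, maf, noise_sd, n, pathway, rep_seed)
        cohort = simulate_cohort(cfg)
        scorer = GrsScorer(pathway=pathway)
        scorer.fit(
            cohort.genotypes,
            cohort.participants["fip"].to_numpy(),
            sex=cohort.participants["sex"].to_numpy(),
            bmi=cohort.participants["bmi"].to_numpy(),
        )
        selected = len(scorer.definition_) > 0
        sign = scorer.definition_.entries[0][1] if selected else 0
        rows.append({"replicate": rep, "selected": selected, "sign": sign})
    return pd.DataFrame(rows)


def obs_weight_experiment(
    beta: float,
    n: int,
    n_replicates: int,
    component: str = "vitamin_c",
    noise_sd: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated simulate-fit cycles for one planted OBS component effect.

    Returns one row per replicate: the estimated beta, whether its sign
    matches the planted sign, and whether the 95% CI covers the truth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        base = SimulationConfig(n_participants=n, noise_sd=noise_sd, seed=rep_seed)
        cont = dict(base.continuous_components)
        cont[component] = ContinuousComponent(
            cont[component].mean, cont[component].sd, beta=beta
        )
        cohort = simulate_cohort(base.with_(continuous_components=cont))
        scorer = ObsScorer()
        scorer.fit(cohort.participants, cohort.participants["fip"].to_numpy())
        w = scorer.weights_.weights.set_index("column")
        est = w.loc[component]
        rows.append(
            {
                "replicate": rep,
                "beta_hat": est["beta"],
                "sign_correct": bool(np.sign(est["beta"]) == np.sign(beta)),
                "ci_covers": bool(est["ci_low"] <= beta <= est["ci_high"]),
            }
        )
    return pd.DataFrame(rows)


def _rate_with_se(k: int, n: int):
    rate = k / n if n else np.nan
    se = float(np.sqrt(rate * (1 - rate) / n)) if n else np.nan
    return rate, se


def recovery_experiment(sim_grid, n_replicates: int = 500, seed: int = 0) -> pd.DataFrame:
    """Aggregate selection and estimation performance over a scenario grid.

    ``sim_grid`` is a sequence of dicts.  SNP scenarios carry keys
    ``effect, maf, noise_sd, n`` (and optionally ``pathway``); OBS
    scenarios carry ``beta, n`` (and optionally ``component``).  Each
    row of the report gives the scenario, the estimated rates
    (selection rate, sign accuracy among selections, or sign-recovery
    and CI-coverage rates) and their binomial Monte-Carlo SEs.
    """
    rows = []
    for i, scen in enumerate(sim_grid):
        scen_seed = seed + 7919 * i
        if "beta" in scen:
            df = obs_weight_experiment(
                scen["beta"],
                scen["n"],
                n_replicates,
                component=scen.get("component", "vitamin_c"),
                noise_sd=scen.get("noise_sd", 0.35),
                seed=scen_seed,
            )
            sign_rate, sign_se = _rate_with_se(int(df["sign_correct"].sum()), len(df))
            cov_rate, cov_se = _rate_with_se(int(df["ci_covers"].sum()), len(df))
            rows.append(
                {
                    **scen,
                    "kind": "obs_weight",
                    "n_replicates": n_replicates,
                    "sign_recovery_rate": sign_rate,
                    "sign_recovery_se": sign_se,
                    "ci_coverage": cov_rate,
                    "ci_coverage_se": cov_se,
                }
            )
        else:
            df = snp_selection_experiment(
                scen.get("effect", 1.0),
                scen["maf"],
                scen.get("noise_sd", 0.35),
                scen["n"],
                n_replicates,
                pathway=scen.get("pathway", "BER"),
                seed=scen_seed,
            )
            sel_rate, sel_se = _rate_with_se(int(df["selected"].sum()), len(df))
            n_sel = int(df["selected"].sum())
            truth_sign = np.sign(np.log(scen.get("effect", 1.0))) or 1
            sign_ok = int((df.loc[df["selected"], "sign"] == truth_sign).sum())
            sign_rate, sign_se = _rate_with_se(sign_ok, n_sel) if n_sel else (np.nan, np.nan)
            rows.append(
                {
                    **scen,
                    "kind": "snp_selection",
                    "n_replicates": n_replicates,
                    "selection_rate": sel_rate,
                    "selection_se": sel_se,
                    "sign_accuracy": sign_rate,
                    "sign_accuracy_se": sign_se,
                }
            )
    return pd.DataFrame(rows)
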