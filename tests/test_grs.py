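"""GRS construction: adjusted means, proportional differences, selection, scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxibalance import (
    GrsScorer,
    SimulationConfig,
    SnpSpec,
    adjusted_genotype_means,
    compute_grs,
    proportional_difference,
    select_snps,
    simulate_cohort,
)
from oxibalance._errors import ConfigurationError
from oxibalance.grs import DEFAULT_SELECTION_RULES, GrsDefinition
from oxibalance.qc import GenotypeCoding


class TestProportionalDifference:
    @pytest.mark.parametrize(
        "comparison,reference,expected",
        [
            (87.0, 71.8, 21.2),
            (85.9, 76.8, 11.8),
            (92.0, 69.1, 33.1),
            (74.9, 109.5, -31.6),
            (72.3, 94.2, -23.2),
        ],
    )
    def test_reported_study_arithmetic(self, comparison, reference, expected):
        assert round(proportional_difference(comparison, reference), 1) == expected

    def test_identity_is_zero(self):
        assert proportional_difference(83.2, 83.2) == 0.0

    @given(
        c=st.floats(1.0, 500.0),
        r1=st.floats(1.0, 500.0),
        r2=st.floats(1.0, 500.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_anti_monotone_in_reference(self, c, r1, r2):
        if r1 < r2:
            assert proportional_difference(c, r1) >= proportional_difference(c, r2)
        sign = np.sign(proportional_difference(c, r1))
        assert sign == np.sign(c - r1)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ConfigurationError, match="positive"):
            proportional_difference(80.0, 0.0)


class TestAdjustedGenotypeMeans:
    def test_no_covariates_equals_brute_force_geometric_means(self):
        rng = np.random.default_rng(0)
        dosages = np.repeat([0, 1, 2], [60, 30, 15])
        fip = rng.lognormal(4.4, 0.3, len(dosages))
        out = adjusted_genotype_means(dosages, fip, snp_id="rs1")
        for cat, sel in (("common_hom", dosages == 0), ("het", dosages == 1), ("var_hom", dosages == 2)):
            expected = math.exp(np.log(fip[sel]).mean())
            got = float(out.loc[out["category"] == cat, "adj_geometric_mean"].iloc[0])
            assert got == pytest.approx(expected, rel=1e-10)

    def test_identical_groups_have_zero_proportional_difference(self):
        dosages = np.repeat([0, 1, 2], 40)
        fip = np.tile([70.0, 80.0, 90.0, 100.0], 30)
        out = adjusted_genotype_means(dosages, fip)
        assert set(out["category"]) == {"common_hom", "het", "var_hom"}
        for cat in ("het", "var_hom"):
            row = out[out["category"] == cat].iloc[0]
            assert row["prop_diff"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_multiplicative_effect_recovered_noise_free(self):
        cfg = SimulationConfig(
            n_participants=400,
            snp_panel=(SnpSpec("rs1", "G", "BER", 0.3),),
            planted_snp_effects={"rs1": 1.2},
            continuous_components={},
            categorical_components={},
            noise_sd=0.0,
            missing_genotype_rate=0.0,
            seed=5,
        )
        cohort = simulate_cohort(cfg)
        out = adjusted_genotype_means(
            cohort.genotypes["rs1"],
            cohort.participants["fip"],
            sex=cohort.participants["sex"],
            bmi=cohort.participants["bmi"],
            snp_id="rs1",
        )
        het = out[out["category"] == "het"].iloc[0]
        assert het["prop_diff"] == pytest.approx(20.0, abs=1e-8)
        var = out[out["category"] == "var_hom"]
        if len(var):
            assert var.iloc[0]["prop_diff"] == pytest.approx(44.0, abs=1e-8)


def _effects_row(snp, prop_diff, p, coding_mode="dosage"):
    return {
        "snp": snp,
        "category": "het",
        "coding_mode": coding_mode,
        "n": 50,
        "adj_geometric_mean": 80.0 * (1 + prop_diff / 100),
        "ci_low": np.nan,
        "ci_high": np.nan,
        "prop_diff": prop_diff,
        "p": p,
        "sign": 1 if prop_diff > 0 else -1,
    }


class TestSelection:
    def test_ber_rule_selects_large_imprecise_effect(self):
        effects = pd.DataFrame([_effects_row("rs1", 12.0, 0.10)])
        d = select_snps(effects, "BER")
        assert [(e[0], e[1]) for e in d.entries] == [("rs1", 1)]

    def test_pathway_rules_differ_for_moderate_precise_effect(self):
        effects = pd.DataFrame([_effects_row("rs1", 8.0, 0.03)])
        assert len(select_snps(effects, "BER")) == 0  # needs >10%
        assert len(select_snps(effects, "AE")) == 1  # >5% with p<=0.05

    def test_negative_difference_selected_with_negative_sign(self):
        effects = pd.DataFrame([_effects_row("rs1", -12.0, 0.10)])
        d = select_snps(effects, "BER")
        assert d.entries[0][1] == -1

    def test_thresholds_are_strict_on_magnitude_and_lenient_on_p(self):
        assert len(select_snps(pd.DataFrame([_effects_row("r", 10.0, 0.01)]), "BER")) == 0
        assert len(select_snps(pd.DataFrame([_effects_row("r", 10.1, 0.15)]), "BER")) == 1
        assert len(select_snps(pd.DataFrame([_effects_row("r", 10.1, 0.16)]), "BER")) == 0

    def test_sign_from_largest_magnitude_qualifying_category(self):
        rows = [
            _effects_row("rs1", 11.0, 0.05),
            dict(_effects_row("rs1", -15.0, 0.10), category="var_hom"),
        ]
        d = select_snps(pd.DataFrame(rows), "BER")
        assert d.entries[0][1] == -1


class TestComputeGrs:
    def test_signed_dosage_sum(self):
        g = pd.DataFrame({"participant_id": ["a"], "rs1": [1.0], "rs2": [2.0]})
        d = GrsDefinition("BER", [("rs1", 1, "dosage"), ("rs2", -1, "dosage")])
        assert compute_grs(g, d).loc["a"] == -1

    def test_all_common_homozygotes_score_zero(self):
        g = pd.DataFrame({"participant_id": list("abc"), "rs1": [0.0] * 3})
        d = GrsDefinition("AE", [("rs1", 1, "dosage")])
        assert (compute_grs(g, d) == 0).all()

    def test_carrier_coding_caps_contribution_at_one(self):
        g = pd.DataFrame({"participant_id": ["a", "b"], "rs1": [2.0, 1.0]})
        d = GrsDefinition("BER", [("rs1", 1, "carrier")])
        assert compute_grs(g, d).tolist() == [1, 1]

    def test_missing_genotype_contributes_zero_and_is_counted(self):
        g = pd.DataFrame({"participant_id": ["a", "b"], "rs1": [np.nan, 2.0]})
        d = GrsDefinition("BER", [("rs1", -1, "dosage")])
        score, n_missing = compute_grs(g, d, return_missing=True)
        assert score.tolist() == [0, -2]
        assert n_missing.tolist() == [1, 0]

    def test_score_bounded_by_definition(self):
        rng = np.random.default_rng(3)
        g = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(200)],
                "rs1": rng.integers(0, 3, 200).astype(float),
                "rs2": rng.integers(0, 3, 200).astype(float),
            }
        )
        d = GrsDefinition("BER", [("rs1", 1, "dosage"), ("rs2", -1, "carrier")])
        s = compute_grs(g, d)
        assert s.abs().max() <= 2 + 1

    def test_absent_snp_is_an_error(self):
        g = pd.DataFrame({"participant_id": ["a"], "rs1": [1.0]})
        d = GrsDefinition("BER", [("rs9", 1, "dosage")])
        with pytest.raises(ConfigurationError, match="rs9"):
            compute_grs(g, d)

    def test_empty_definition_is_an_error(self):
        g = pd.DataFrame({"participant_id": ["a"], "rs1": [1.0]})
        with pytest.raises(ConfigurationError, match="empty"):
            compute_grs(g, GrsDefinition("BER", []))


class TestGrsScorer:
    def test_fit_recovers_strong_planted_snp(self):
        cfg = SimulationConfig(
            n_participants=500,
            snp_panel=(
                SnpSpec("hit", "G1", "BER", 0.3),
                SnpSpec("null", "G2", "BER", 0.3),
            ),
            planted_snp_effects={"hit": 1.5},
            continuous_components={},
            categorical_components={},
            noise_sd=0.2,
            missing_genotype_rate=0.0,
            seed=10,
        )
        cohort = simulate_cohort(cfg)
        scorer = GrsScorer(pathway="BER").fit(
            cohort.genotypes,
            cohort.participants["fip"],
            sex=cohort.participants["sex"],
            bmi=cohort.participants["bmi"],
        )
        selected = {e[0]: e[1] for e in scorer.definition_.entries}
        assert selected.get("hit") == 1
        scores = scorer.transform(cohort.genotypes)
        # the score is dominated by the planted SNP's dosage
        assert np.corrcoef(scores, cohort.genotypes["hit"])[0, 1] > 0.9

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        scorer = GrsScorer(pathway="AE", collapse_threshold=5)
        params = scorer.get_params()
        assert params["pathway"] == "AE" and params["collapse_threshold"] == 5
        clone(scorer)  # must be cloneable for pipelines/model selection
        scorer.set_params(missing_policy="mean")
        assert scorer.missing_policy == "mean"

    def test_definition_save_load_round_trip(self, tmp_path):
        d = GrsDefinition(
            "AE", [("rs1", 1, "dosage"), ("rs2", -1, "carrier")], DEFAULT_SELECTION_RULES["AE"]
        )
        path = tmp_path / "def.yaml"
        d.save(path)
        d2 = GrsDefinition.load(path)
        assert d2.pathway == "AE"
        assert d2.entries == d.entries
        assert d2.selection_rule.criteria == d.selection_rule.criteria
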