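"""Category assignment and adjusted geometric-mean comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oxibalance import (
    SimulationConfig,
    SnpSpec,
    adjusted_means_by_category,
    assign_categories,
    joint_grs_analysis,
    simulate_cohort,
    stratified_association,
)
from oxibalance._errors import ConfigurationError, ModelError
from oxibalance.association import CategorySpec


class TestAssignCategories:
    def test_nine_distinct_scores_split_evenly(self):
        labels, medians = assign_categories(np.arange(1, 10))
        assert labels.value_counts().sort_index().tolist() == [3, 3, 3]
        assert medians == {1: 2.0, 2: 5.0, 3: 8.0}

    def test_ties_are_unsplit_giving_unequal_tertiles(self):
        scores = np.array([0] * 5 + [1] * 8 + [2] * 3 + [4] * 2)
        labels, _ = assign_categories(scores)
        sizes = labels.value_counts().sort_index().tolist()
        assert sum(sizes) == 18
        assert sizes != [6, 6, 6]
        # all copies of each tied value share one category
        for v in (0, 1, 2, 4):
            assert labels[scores == v].nunique() == 1

    def test_dichotomy_cutpoint_is_inclusive_on_high_side(self):
        labels, _ = assign_categories([1, 2, 3], CategorySpec("dichotomy", 2))
        assert labels.tolist() == [1, 2, 2]  # low (<2) / high (>=2)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ConfigurationError, match="distinct"):
            assign_categories([1, 1, 2, 2])


class TestAdjustedMeans:
    def test_covariate_free_equals_closed_form_geometric_mean_and_ci(self):
        rng = np.random.default_rng(4)
        fip = rng.lognormal(4.4, 0.3, 40)
        table = adjusted_means_by_category(fip, np.ones(40, dtype=int))
        log = np.log(fip)
        gm = math.exp(log.mean())
        se = log.std(ddof=1) / math.sqrt(40)
        tq = stats.t.ppf(0.975, 39)
        row = table.iloc[0]
        assert row["geometric_mean"] == pytest.approx(gm, rel=1e-10)
        assert row["ci_low"] == pytest.approx(math.exp(log.mean() - tq * se), rel=1e-10)
        assert row["ci_high"] == pytest.approx(math.exp(log.mean() + tq * se), rel=1e-10)

    def test_no_covariate_model_reproduces_raw_geometric_means_per_group(self):
        rng = np.random.default_rng(5)
        fip = rng.lognormal(4.4, 0.35, 90)
        labels = np.repeat([1, 2, 3], 30)
        table = adjusted_means_by_category(fip, labels)
        for c in (1, 2, 3):
            expected = math.exp(np.log(fip[labels == c]).mean())
            got = float(table.loc[table["category"] == c, "geometric_mean"].iloc[0])
            assert got == pytest.approx(expected, rel=1e-10)

    def test_reference_category_labelled_ref(self):
        rng = np.random.default_rng(6)
        table = adjusted_means_by_category(
            rng.lognormal(4.4, 0.3, 60), np.repeat([1, 2], 30)
        )
        assert table["prop_diff_label"].iloc[0] == "Ref."
        assert np.isnan(table["p_vs_ref"].iloc[0])
        assert (table["ci_low"] < table["geometric_mean"]).all()
        assert (table["geometric_mean"] < table["ci_high"]).all()

    def test_contrast_p_uniform_under_permuted_labels(self):
        rng = np.random.default_rng(7)
        fip = rng.lognormal(4.4, 0.3, 120)
        pvals = []
        for _ in range(200):
            labels = rng.permutation(np.repeat([1, 2, 3], 40))
            t = adjusted_means_by_category(fip, labels)
            pvals.append(t.attrs["p_contrast"])
        frac = np.mean(np.array(pvals) <= 0.05)
        assert abs(frac - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 200)

    def test_monotone_dose_response_recovered(self):
        """Planted per-point score effect on ln FiP yields monotone tertile
        means in >= 95% of simulations (effect 0.04/point, n = 245, and a
        12-SNP score emulating the study's 12-SNP repair-pathway score)."""
        panel = tuple(SnpSpec(f"rs{i}", "G", "BER", 0.4) for i in range(12))
        effects = {f"rs{i}": math.exp(0.04) for i in range(12)}
        monotone = 0
        n_reps = 200
        for rep in range(n_reps):
            cfg = SimulationConfig(
                n_participants=245,
                snp_panel=panel,
                planted_snp_effects=effects,
                continuous_components={},
                categorical_components={},
                noise_sd=0.35,
                missing_genotype_rate=0.0,
                seed=5000 + rep,
            )
            cohort = simulate_cohort(cfg)
            score = cohort.genotypes[[f"rs{i}" for i in range(12)]].sum(axis=1)
            labels, _ = assign_categories(score)
            t = adjusted_means_by_category(
                cohort.participants["fip"].values,
                labels.values,
                cohort.participants[["sex"]],
            )
            gms = t["geometric_mean"].to_numpy()
            monotone += bool(np.all(np.diff(gms) > 0))
        assert monotone / n_reps >= 0.95

    def test_nonpositive_fip_rejected(self):
        with pytest.raises(ConfigurationError, match="positive"):
            adjusted_means_by_category([80.0, -1.0], [1, 2])


class TestStratifiedAndJoint:
    @staticmethod
    def _cohort(n=600, seed=31, obs_beta=-0.1):
        cfg = SimulationConfig(n_participants=n, seed=seed)
        from oxibalance import ContinuousComponent

        cont = dict(cfg.continuous_components)
        cont["vitamin_c"] = ContinuousComponent(55.0, 136.0, beta=obs_beta)
        return simulate_cohort(cfg.with_(continuous_components=cont))

    def test_stratified_tables_and_interaction_p(self):
        cohort = self._cohort()
        p = cohort.participants
        rng = np.random.default_rng(0)
        grs = pd.Series(rng.integers(0, 4, len(p)))
        obs_labels, _ = assign_categories(p["vitamin_c"].values)
        di = pd.Series(np.where(grs < 2, 1, 2))
        res = stratified_association(
            p["fip"].values, obs_labels.values, di.values, p[["sex"]]
        )
        assert set(res["strata"]) == {1, 2}
        for table in res["strata"].values():
            assert len(table) == 3
        assert 0 <= res["p_interaction"] <= 1
        assert 0 <= res["p_interaction_dummy"] <= 1

    def test_interaction_p_uniform_when_effect_is_identical_in_strata(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(150):
            n = 240
            obs_t = rng.integers(1, 4, n)
            grs_hi = rng.integers(1, 3, n)
            ln_fip = 4.4 - 0.1 * obs_t + rng.normal(0, 0.35, n)  # same slope everywhere
            res = stratified_association(np.exp(ln_fip), obs_t, grs_hi, None)
            pvals.append(res["p_interaction"])
        frac = np.mean(np.array(pvals) <= 0.05)
        assert abs(frac - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 150)

    def test_stratum_with_empty_tertile_rejected(self):
        fip = [80.0] * 6
        obs_t = [1, 2, 3, 1, 2, 2]
        grs = [1, 1, 1, 2, 2, 2]  # stratum 2 has no tertile 3
        with pytest.raises(ModelError, match="empty"):
            stratified_association(fip, obs_t, grs, None)

    def test_joint_cells_sum_to_total_and_reproduce_additive_effects(self):
        rng = np.random.default_rng(9)
        n = 2000
        ae = rng.integers(1, 3, n)
        ber = rng.integers(1, 3, n)
        # additive log-scale effects: AE high +0.10, BER high +0.15
        ln_fip = 4.4 + 0.10 * (ae == 2) + 0.15 * (ber == 2)
        table = joint_grs_analysis(np.exp(ln_fip), ae, ber)
        assert table["n"].sum() == n
        hh = table.loc[table["category"] == "AE_high/BER_high"].iloc[0]
        expected = (math.exp(0.10 + 0.15) - 1) * 100
        assert hh["prop_diff"] == pytest.approx(expected, abs=1e-6)

    def test_joint_all_null_cells_agree_within_sampling_error(self):
        rng = np.random.default_rng(10)
        n = 800
        fip = rng.lognormal(4.4, 0.3, n)
        table = joint_grs_analysis(fip, rng.integers(1, 3, n), rng.integers(1, 3, n))
        gms = table["geometric_mean"]
        assert (gms.max() - gms.min()) / gms.min() < 0.10
        assert (table.loc[1:, "p_vs_ref"] > 0.001).all()

    def test_joint_empty_cell_rejected(self):
        with pytest.raises(ModelError, match="empty"):
            joint_grs_analysis([80.0, 90.0, 85.0], [1, 1, 2], [1, 2, 1])

    def test_joint_bar_chart_renders(self, tmp_path):
        from oxibalance.association import plot_joint_analysis

        rng = np.random.default_rng(11)
        n = 400
        table = joint_grs_analysis(
            rng.lognormal(4.4, 0.3, n), rng.integers(1, 3, n), rng.integers(1, 3, n)
        )
        out = tmp_path / "joint.png"
        plot_joint_analysis(table, out)
        assert out.stat().st_size > 0
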