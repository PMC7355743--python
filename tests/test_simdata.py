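"""Synthetic-data generator: determinism, engineered QC properties,
phenotype variance scaling, environment/trajectory/RCT structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedigrs import genoqc, simdata
from pedigrs.errors import ConfigurationError, DataError


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"h2_target": 1.0},
            {"n_snps": -1},
            {"n_qc_fail_callrate": 50, "n_qc_fail_hwe": 10, "n_snps": 56},
            {"missing_rate": 0.2},
            {"env_kind": "fancy"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            simdata.SimConfig(seed=0, **kwargs)


class TestPanel:
    def test_deterministic_under_fixed_seed(self):
        cfg = simdata.SimConfig(n_snps=44, seed=7)
        p1, _ = simdata.simulate_panel(cfg)
        p2, _ = simdata.simulate_panel(cfg)
        assert len(p1) == 44
        pd.testing.assert_frame_equal(p1, p2)

    def test_empty_panel_is_allowed(self):
        cfg = simdata.SimConfig(n_snps=0, n_qc_fail_callrate=0,
                                n_qc_fail_hwe=0, seed=1)
        panel, _ = simdata.simulate_panel(cfg)
        assert len(panel) == 0

    def test_frequencies_respect_the_configured_range(self):
        cfg = simdata.SimConfig(n_snps=300, maf_range=(0.1, 0.5),
                                n_qc_fail_callrate=0, n_qc_fail_hwe=0, seed=3)
        panel, truth = simdata.simulate_panel(cfg)
        assert ((panel["freq"] >= 0.1) & (panel["freq"] <= 0.5)).all()
        np.testing.assert_array_equal(panel["freq"], truth.allele_freqs)

    def test_alleles_differ_and_betas_positive(self):
        cfg = simdata.SimConfig(n_snps=50, seed=5, n_qc_fail_callrate=0,
                                n_qc_fail_hwe=0)
        panel, _ = simdata.simulate_panel(cfg)
        assert (panel["risk_allele"] != panel["other_allele"]).all()
        assert (panel["beta"] >= 0).all()


class TestGenotypes:
    def test_byte_identical_under_fixed_seed(self, qc_config, qc_fixture):
        panel, genotypes, _ = qc_fixture
        panel2, _ = simdata.simulate_panel(qc_config)
        genotypes2, _ = simdata.simulate_genotypes(panel2, qc_config)
        np.testing.assert_array_equal(genotypes.alleles, genotypes2.alleles)

    def test_no_missing_when_rate_zero_and_no_failures(self):
        cfg = simdata.SimConfig(n_snps=10, n_qc_fail_callrate=0,
                                n_qc_fail_hwe=0, missing_rate=0.0,
                                n_individuals=200, seed=11)
        panel, _ = simdata.simulate_panel(cfg)
        geno, _ = simdata.simulate_genotypes(panel, cfg)
        assert (genoqc.call_rate(geno) == 1.0).all()

    def test_genotype_frequencies_match_hwe_at_large_n(self):
        cfg = simdata.SimConfig(n_snps=1, n_qc_fail_callrate=0,
                                n_qc_fail_hwe=0, missing_rate=0.0,
                                n_individuals=10_000, seed=13)
        panel, _ = simdata.simulate_panel(cfg)
        panel = panel.assign(freq=0.3)
        geno, _ = simdata.simulate_genotypes(panel, cfg)
        counts = genoqc.genotype_counts(geno, panel).iloc[0]
        n = 10_000
        observed = np.array([counts["n_hh"], counts["n_rh"], counts["n_rr"]]) / n
        expected = np.array([0.49, 0.42, 0.09])
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(observed - expected) < 3 * se).all()

    def test_engineered_failures_fail_their_criterion(self, qc_fixture):
        panel, genotypes, truth = qc_fixture
        rates = genoqc.call_rate(genotypes)
        assert (rates[list(truth.qc_fail_callrate)] < 0.95).all()
        counts = genoqc.genotype_counts(genotypes, panel).set_index("snp_id")
        for snp in truth.qc_fail_hwe:
            c = counts.loc[snp]
            p = genoqc.hwe_exact_test(int(c.n_rr), int(c.n_rh), int(c.n_hh))
            assert p < 1e-3

    def test_too_small_n_raises_naming_minimum(self):
        cfg = simdata.SimConfig(n_snps=5, n_qc_fail_callrate=0,
                                n_qc_fail_hwe=1, n_individuals=20, seed=17)
        panel, _ = simdata.simulate_panel(cfg)
        with pytest.raises(ConfigurationError, match="at least n="):
            simdata.simulate_genotypes(panel, cfg)

    def test_empty_panel_is_an_error(self):
        cfg = simdata.SimConfig(n_snps=0, n_qc_fail_callrate=0,
                                n_qc_fail_hwe=0, seed=1)
        panel, _ = simdata.simulate_panel(cfg)
        with pytest.raises(DataError):
            simdata.simulate_genotypes(panel, cfg)


class TestPhenotypes:
    def test_null_heritability_gives_null_slope(self):
        from pedigrs import assoc, score as score_mod

        hits = 0
        for seed in range(20):
            cfg = simdata.SimConfig(n_snps=20, n_qc_fail_callrate=0,
                                    n_qc_fail_hwe=0, missing_rate=0.0,
                                    n_individuals=500, h2_target=0.0, seed=seed)
            panel, _ = simdata.simulate_panel(cfg)
            geno, _ = simdata.simulate_genotypes(panel, cfg)
            dosage = genoqc.to_dosage(geno, panel)
            cohort, _ = simdata.simulate_phenotypes(dosage, panel, cfg)
            s = score_mod.compute_pgrs(dosage, panel)
            res, _ = assoc.fit_linear(
                cohort.set_index("id")["bmi_z"].set_axis(s.index), s
            )
            if abs(res.stat) < 3:
                hits += 1
        assert hits >= 17  # |t| < 3 should hold in the vast majority of seeds

    def test_variance_explained_near_target_at_large_n(self, scored_cohort):
        truth = scored_cohort["truth"]
        assert truth.realized_h2 == pytest.approx(0.05, abs=0.02)

    def test_weight_status_consistent_with_cutoffs(self, scored_cohort):
        cohort = scored_cohort["cohort"]
        ow, ob = scored_cohort["config"].bmiz_cutoffs
        assert (cohort.loc[cohort.weight_status == "OB", "bmi_z"] >= ob).all()
        assert (cohort.loc[cohort.weight_status == "NW", "bmi_z"] < ow).all()

    def test_incomplete_dosage_rejected(self, clean_config):
        panel, _ = simdata.simulate_panel(clean_config)
        geno, _ = simdata.simulate_genotypes(panel, clean_config)
        dosage = genoqc.to_dosage(geno, panel)
        dosage.values[0, 0] = np.nan
        with pytest.raises(DataError):
            simdata.simulate_phenotypes(dosage, panel, clean_config)


class TestEnvironment:
    def test_adds_the_configured_number_of_factors(self, scored_cohort):
        cfg = simdata.SimConfig(seed=1, n_env_factors=47)
        out = simdata.simulate_environment(
            scored_cohort["cohort"].reset_index(), cfg
        )
        env_cols = [c for c in out.columns if c.startswith("env_")]
        assert len(env_cols) == 47

    def test_effect_count_exceeding_factor_count_is_an_error(self):
        cfg = simdata.SimConfig(seed=1, n_env_factors=1,
                                gxe_effects={0: 0.5})
        cfg2 = simdata.SimConfig(seed=1, n_env_factors=1,
                                 gxe_effects={1: 0.5})
        cohort = pd.DataFrame({"bmi_z": [0.0], "pgrs": [1.0]})
        simdata.simulate_environment(cohort, cfg)  # one effect, one factor: fine
        with pytest.raises(ConfigurationError):
            simdata.simulate_environment(cohort, cfg2)

    def test_interaction_coefficient_recovered(self, scored_cohort):
        from pedigrs import gxe

        cfg = simdata.SimConfig(seed=23, n_env_factors=3,
                                gxe_effects={"env_01": 0.5})
        cohort = simdata.simulate_environment(
            scored_cohort["cohort"].reset_index(), cfg
        )
        res = gxe.interaction_fit(cohort, "env_01")
        assert abs(res.beta3 - 0.5) < 2 * res.se


class TestLongitudinal:
    def test_bookkeeping_96_individuals_two_rows_each(self):
        cfg = simdata.SimConfig(seed=29, group_sizes=(20, 20, 20, 20, 16))
        cohort, truth = simdata.simulate_longitudinal(cfg)
        assert cohort["id"].nunique() == 96
        assert len(cohort) == 192
        assert sorted(truth.group_labels.value_counts()) == [16, 20, 20, 20, 20]
        assert truth.group_labels.nunique() == 5

    def test_reference_group_never_insulin_resistant(self):
        from pedigrs.longi import IR_CUTOFFS_DEFAULT, classify_ir

        cfg = simdata.SimConfig(seed=31)
        cohort, _ = simdata.simulate_longitudinal(cfg)
        ref = cohort[cohort.group == "NW_nonIR_stable"]
        t0 = ref[ref.timepoint == "T0"]
        t1 = ref[ref.timepoint == "T1"]
        assert (t0["homa_ir"] < 2.5).all()
        for _, row in t1.iterrows():
            assert not classify_ir(row.homa_ir, row.sex, row.tanner,
                                   IR_CUTOFFS_DEFAULT)

    def test_score_enrichment_detected_at_large_n(self):
        from pedigrs import longi

        cfg = simdata.SimConfig(
            seed=37, group_sizes=(400, 400, 400, 400, 400),
            trajectory_enrichment={"OWOB_persistent_IR": 3.0},
        )
        cohort, truth = simdata.simulate_longitudinal(cfg)
        scores = cohort.drop_duplicates("id").set_index("id")["pgrs"]
        table = longi.tertile_trajectory_or(scores, truth.group_labels)
        row = table.set_index("group").loc["OWOB_persistent_IR"]
        assert row["odds_ratio"] > 1 and row["p"] < 0.05


class TestRct:
    def test_default_arm_sizes_match_design(self):
        cfg = simdata.SimConfig(seed=41)
        cohort, _ = simdata.simulate_rct(cfg)
        assert cohort["id"].nunique() == 124
        assert len(cohort) == 248
        arms = cohort.drop_duplicates("id")["arm"].value_counts()
        assert arms["placebo"] == 59 and arms["treated"] == 65

    def test_null_interaction_p_values_are_uniform(self):
        """Under a zero score x treatment effect the interaction p-value
        should be uniform across repeated trials (KS test)."""
        from pedigrs import pharmaco

        pvals = []
        for seed in range(200):
            cfg = simdata.SimConfig(seed=seed, rct_interaction=0.0)
            rct, _ = simdata.simulate_rct(cfg)
            pvals.append(pharmaco.drug_response_interaction(rct).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_interaction_recovered_at_large_n(self):
        """The mean estimate over several trials matches the simulated
        score x treatment effect within Monte-Carlo error."""
        from pedigrs import pharmaco

        ests = []
        for seed in range(10):
            cfg = simdata.SimConfig(seed=seed, rct_interaction=0.4,
                                    rct_arm_sizes=(2000, 2000))
            rct, _ = simdata.simulate_rct(cfg)
            ests.append(pharmaco.drug_response_interaction(rct).estimate)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.4) < 3 * mc_se
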