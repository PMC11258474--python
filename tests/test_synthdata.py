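"""Generators: determinism, LD structure, allele frequencies, cohort model."""

import numpy as np
import pytest
from dataclasses import replace

from bpfrail.frailty import compute_fi
from bpfrail.synthdata import (
    LdBlock,
    SimulationConfig,
    SummaryScenarioConfig,
    simulate_cohort,
    simulate_genotypes,
    simulate_summary_scenario,
)


def _config(blocks, n=10_000, seed=1, **kw):
    return SimulationConfig(n_individuals=n, ld_blocks=blocks, seed=seed, **kw)


class TestGenotypes:
    def test_same_seed_identical(self, small_config):
        a = simulate_genotypes(small_config)
        b = simulate_genotypes(small_config)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snps.equals(b.snps)

    def test_different_seed_differs(self, small_config):
        a = simulate_genotypes(small_config)
        b = simulate_genotypes(replace(small_config, seed=small_config.seed + 1))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_independent_snps_uncorrelated(self):
        cfg = _config([LdBlock(n_snps=6, maf_range=(0.5, 0.5), rho=0.0)], n=10_000)
        geno = simulate_genotypes(cfg)
        r = np.corrcoef(geno.dosages, rowvar=False)
        off = r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_high_rho_gives_strong_dosage_ld(self):
        cfg = _config([LdBlock(n_snps=2, maf_range=(0.3, 0.3), rho=0.9)], n=10_000)
        geno = simulate_genotypes(cfg)
        r = np.corrcoef(geno.dosages[:, 0], geno.dosages[:, 1])[0, 1]
        assert r**2 > 0.5

    def test_maf_near_target(self):
        cfg = _config([LdBlock(n_snps=8, maf_range=(0.05, 0.45), rho=0.2)], n=20_000)
        geno = simulate_genotypes(cfg)
        target = geno.snps["maf"].to_numpy()
        observed = geno.observed_maf()
        # binomial MC error on the allele frequency, 2n draws per SNP
        se = np.sqrt(target * (1 - target) / (2 * cfg.n_individuals))
        assert (np.abs(observed - target) < np.maximum(3 * se, 0.05)).all()
        assert np.abs(observed - target).max() < 0.05

    def test_dosages_in_range_and_complete(self, small_genotypes):
        assert not np.isnan(small_genotypes.dosages).any()
        assert set(np.unique(small_genotypes.dosages)) <= {0.0, 1.0, 2.0}

    @pytest.mark.parametrize(
        "block",
        [
            LdBlock(n_snps=0),
            LdBlock(n_snps=2, rho=1.0),
            LdBlock(n_snps=2, maf_range=(0.0, 0.3)),
            LdBlock(n_snps=2, maf_range=(0.4, 0.2)),
        ],
    )
    def test_invalid_blocks_rejected(self, block):
        with pytest.raises(ValueError):
            _config([block]).validate()

    def test_effect_length_mismatch_rejected(self):
        cfg = _config([LdBlock(n_snps=3)], snp_effects_sbp=np.ones(5))
        with pytest.raises(ValueError, match="length"):
            cfg.validate()


class TestCohort:
    def test_null_model_no_bp_fi_correlation(self):
        cfg = _config(
            [LdBlock(n_snps=4)],
            n=20_000,
            theta_sbp=0.0,
            confounder_liability=0.0,
            seed=5,
        )
        geno = simulate_genotypes(cfg)
        cohort = simulate_cohort(geno, cfg)
        fi = compute_fi(cohort.deficits).fi.to_numpy()
        r = np.corrcoef(cohort.phenotypes["true_sbp"], fi)[0, 1]
        assert abs(r) < 0.02

    def test_degenerate_noiseless_bp_constant(self):
        cfg = _config(
            [LdBlock(n_snps=2)],
            n=200,
            snp_effects_sbp=np.zeros(2),
            snp_effects_dbp=np.zeros(2),
            sbp_noise_sd=0.0,
            dbp_noise_sd=0.0,
            confounder_bp=0.0,
            age_effect_sbp=0.0,
            bmi_effect_sbp=0.0,
            sex_effect_sbp=0.0,
            med_prob=0.0,
        )
        cfg = replace(cfg, age_effect_dbp=0.0, bmi_effect_dbp=0.0, sex_effect_dbp=0.0)
        geno = simulate_genotypes(cfg)
        cohort = simulate_cohort(geno, cfg)
        # pc1 keeps a 0.1 mmHg loading; true SBP is constant up to that term
        sbp = cohort.phenotypes["true_sbp"]
        assert sbp.std() < 0.2

    def test_positive_theta_fi_increases_over_sbp_tertiles(self):
        cfg = _config([LdBlock(n_snps=4)], n=20_000, theta_sbp=0.02, seed=9)
        geno = simulate_genotypes(cfg)
        cohort = simulate_cohort(geno, cfg)
        fi = compute_fi(cohort.deficits).fi
        sbp = cohort.phenotypes["true_sbp"]
        tertile = np.searchsorted(np.quantile(sbp, [1 / 3, 2 / 3]), sbp)
        means = [fi[tertile == k].mean() for k in range(3)]
        assert means[0] < means[1] < means[2]

    def test_sbp_exceeds_dbp_everywhere(self, small_cohort):
        phen = small_cohort.phenotypes
        assert (phen["true_sbp"] > phen["true_dbp"]).all()

    def test_medication_shifts_observed_bp_down(self):
        cfg = _config([LdBlock(n_snps=2)], n=30_000, reading_noise_sd=0.0, seed=3)
        geno = simulate_genotypes(cfg)
        phen = simulate_cohort(geno, cfg).phenotypes
        on = phen["on_bp_med"] == 1
        assert on.sum() > 100
        np.testing.assert_allclose(
            phen.loc[on, "sbp_reading1"], phen.loc[on, "true_sbp"] - 15.0
        )
        np.testing.assert_allclose(
            phen.loc[on, "dbp_reading1"], phen.loc[on, "true_dbp"] - 10.0
        )

    def test_covariates_complete(self, small_cohort):
        covs = ["age", "sex", "center", "smoking", "alcohol", "bmi", "deprivation", "array"]
        covs += [f"pc{i}" for i in range(1, 11)]
        assert not small_cohort.phenotypes[covs].isna().any().any()

    def test_multinomial_mode_emits_categories(self):
        cfg = _config(
            [LdBlock(n_snps=2)],
            n=5000,
            outcome_mode="multinomial",
            cat_conf_pre=0.3,
            cat_conf_frail=0.3,
        )
        cohort = simulate_cohort(simulate_genotypes(cfg), cfg)
        counts = cohort.phenotypes["frailty_category"].value_counts()
        assert set(counts.index) == {"non_frail", "pre_frail", "frail"}
        assert cohort.deficits.empty


class TestSummaryScenario:
    def test_noiseless_causal_ratios_equal(self):
        cfg = SummaryScenarioConfig(scenario="causal", se_zx=1e-12, se_zy=1e-12, seed=2)
        sc = simulate_summary_scenario(cfg)
        ratio = sc.records["b_zy"] / sc.records["b_zx"]
        np.testing.assert_allclose(ratio, cfg.b_xy_true, rtol=1e-6)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            simulate_summary_scenario(SummaryScenarioConfig(scenario="wormhole"))

    def test_ld_symmetric_psd_unit_diagonal(self):
        sc = simulate_summary_scenario(SummaryScenarioConfig(scenario="linkage", seed=4))
        assert np.allclose(sc.ld, sc.ld.T)
        assert np.allclose(np.diag(sc.ld), 1.0)
        assert np.linalg.eigvalsh(sc.ld).min() > -1e-10

    def test_seeded_determinism(self):
        a = simulate_summary_scenario(SummaryScenarioConfig(seed=8))
        b = simulate_summary_scenario(SummaryScenarioConfig(seed=8))
        assert a.records.equals(b.records)

    def test_null_scenario_centres_outcome_on_zero(self):
        cfg = SummaryScenarioConfig(scenario="null", seed=6)
        sc = simulate_summary_scenario(cfg)
        z = sc.records["b_zy"] / sc.records["se_zy"]
        assert abs(z.mean()) < 1.5
        assert sc.records["p_zx"].min() < 5e-8  # expression signal still present
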