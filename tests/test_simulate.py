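"""Synthetic cohort generator: HWE genotypes, biomarker model, phenome,
kinship, and seed determinism."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mrphewas.simulate import (
    PhecodeScenario,
    ScenarioConfig,
    SnpDef,
    calibrated_snps,
    generate_biomarkers,
    generate_cohort,
    generate_covariates,
    generate_genotypes,
    generate_kinship,
    generate_phenome,
    noise_sd_for_unit_variance,
    write_cohort,
)

from conftest import one_phecode_config


def _config(snps, n=100_000, seed=0, **kw):
    return ScenarioConfig(
        n_individuals=n,
        snps=snps,
        phecode_scenarios=[PhecodeScenario("280.1", 0.05)],
        seed=seed,
        **kw,
    )


class TestGenotypes:
    def test_mean_dosage_matches_binomial_expectation(self):
        cfg = _config([SnpDef("rs1", "A", "G", 0.5, 0.0)])
        g = generate_genotypes(cfg)["rs1"]
        se = math.sqrt(2 * 0.5 * 0.5 / len(g))
        assert abs(g.mean() - 1.0) < 3 * se

    def test_near_zero_frequency_gives_all_zero_column(self):
        cfg = _config([SnpDef("rs1", "A", "G", 1e-9, 0.0)], n=10_000)
        assert (generate_genotypes(cfg)["rs1"] == 0).all()

    def test_genotype_counts_follow_hardy_weinberg(self):
        cfg = _config([SnpDef("rs1", "A", "G", 0.3, 0.0)])
        g = generate_genotypes(cfg)["rs1"].to_numpy()
        observed = np.bincount(g, minlength=3)
        expected = len(g) * np.array([0.49, 0.42, 0.09])
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_dosages_are_integral_in_range(self, small_cohort):
        g = small_cohort.genotypes.to_numpy()
        assert g.min() >= 0 and g.max() <= 2

    def test_out_of_range_eaf_rejected(self):
        with pytest.raises(ValueError):
            SnpDef("rs1", "A", "G", 1.2, 0.0)
        with pytest.raises(ValueError):
            SnpDef("rs1", "A", "G", float("nan"), 0.0)


class TestBiomarkers:
    def test_null_effects_give_null_slope(self):
        snps = [SnpDef("rs1", "A", "G", 0.3, 0.0)]
        cfg = _config(snps, biomarker_noise_sd=1.0)
        g = generate_genotypes(cfg)
        iron = generate_biomarkers(g, cfg)["serum_iron"]
        fit = sm.OLS(iron, sm.add_constant(g["rs1"].astype(float))).fit()
        assert abs(fit.params.iloc[1]) < 3 * fit.bse.iloc[1]

    def test_ols_recovers_configured_per_allele_effects(self, snps):
        cfg = _config(snps, biomarker_noise_sd=noise_sd_for_unit_variance(snps))
        g = generate_genotypes(cfg)
        iron = generate_biomarkers(g, cfg)["serum_iron"]
        fit = sm.OLS(iron, sm.add_constant(g.astype(float))).fit()
        for j, snp in enumerate(snps):
            assert abs(fit.params.iloc[j + 1] - snp.beta_iron_sd_units) < 3 * fit.bse.iloc[j + 1]

    def test_instruments_explain_configured_variance_fraction(self, snps):
        cfg = _config(snps, n=200_000, biomarker_noise_sd=noise_sd_for_unit_variance(snps))
        g = generate_genotypes(cfg)
        iron = generate_biomarkers(g, cfg)["serum_iron"]
        r2 = sm.OLS(iron, sm.add_constant(g.astype(float))).fit().rsquared
        assert r2 == pytest.approx(0.038, abs=0.004)

    def test_slope_error_shrinks_with_sample_size(self, snps):
        # convergence at ~1/sqrt(n): the 3-SE band tightens with n and
        # still covers the configured effect at every scale
        for n in (10**3, 10**4, 10**5):
            cfg = _config(snps, n=n, seed=7, biomarker_noise_sd=noise_sd_for_unit_variance(snps))
            g = generate_genotypes(cfg)
            iron = generate_biomarkers(g, cfg)["serum_iron"]
            fit = sm.OLS(iron, sm.add_constant(g.astype(float))).fit()
            err = abs(fit.params.iloc[3] - snps[2].beta_iron_sd_units)
            assert err < 3 * fit.bse.iloc[3]
            assert fit.bse.iloc[3] < 0.4 / math.sqrt(n) * 10

    def test_concordant_sign_pattern_in_expectation(self, small_cohort):
        score = small_cohort.genotypes.to_numpy(float) @ np.array(
            [s.beta_iron_sd_units for s in small_cohort.config.snps]
        )
        bm = small_cohort.biomarkers
        for col in ("serum_iron", "log10_ferritin", "transferrin_saturation"):
            assert np.corrcoef(score, bm[col])[0, 1] > 0
        assert np.corrcoef(score, bm["transferrin"])[0, 1] < 0

    def test_unit_marginal_variances(self, small_cohort):
        for col in small_cohort.biomarkers:
            assert small_cohort.biomarkers[col].var() == pytest.approx(1.0, abs=0.05)

    def test_negative_noise_sd_rejected(self, snps):
        with pytest.raises(ValueError):
            _config(snps, biomarker_noise_sd=-0.1)


class TestPhenome:
    def test_unmapped_phecode_is_configuration_error(self, snps):
        cfg = one_phecode_config(1000, snp_list=snps)
        g = generate_genotypes(cfg)
        cov = generate_covariates(cfg)
        bm = generate_biomarkers(g, cfg)
        empty_map = pd.DataFrame(
            columns=["icd_version", "icd_code", "phecode", "exclusion_root", "description", "category"]
        )
        with pytest.raises(ValueError, match="no mapped ICD"):
            generate_phenome(g, bm, cov, cfg, phecode_map=empty_map)

    def test_case_fraction_tracks_baseline_prevalence(self, snps):
        cfg = one_phecode_config(50_000, prevalence=0.05, snp_list=snps, seed=5)
        cohort = generate_cohort(cfg)
        frac = cohort.icd_events["person_id"].nunique() / cfg.n_individuals
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_every_event_person_exists_in_covariates(self, small_cohort):
        assert set(small_cohort.icd_events["person_id"]).issubset(
            set(small_cohort.covariates.index)
        )


class TestKinship:
    def test_pairs_disjoint_and_in_range(self, snps):
        cfg = _config(snps, n=1000, n_related_pairs=50, kinship_range=(0.09, 0.25))
        kin = generate_kinship(cfg)
        ids = list(kin["id_a"]) + list(kin["id_b"])
        assert len(ids) == len(set(ids)) == 100
        assert (kin["coefficient"] > 0.0884).all()

    def test_zero_pairs_gives_empty_table(self, snps):
        assert len(generate_kinship(_config(snps, n=100, n_related_pairs=0))) == 0

    def test_too_many_pairs_rejected(self, snps):
        with pytest.raises(ValueError):
            _config(snps, n=10, n_related_pairs=6)

    def test_kinship_ids_exist_in_cohort(self, small_cohort):
        kin = small_cohort.kinship
        cov_ids = set(small_cohort.covariates.index)
        assert set(kin["id_a"]).issubset(cov_ids) and set(kin["id_b"]).issubset(cov_ids)


class TestDeterminism:
    def test_fixed_seed_gives_byte_identical_cohort(self, tmp_path, snps):
        cfg = one_phecode_config(2000, causal_log_or=math.log(0.72), seed=42, snp_list=snps)
        for d in ("a", "b"):
            write_cohort(generate_cohort(cfg), tmp_path / d)
        for name in ("genotypes", "covariates", "biomarkers", "icd_events", "kinship"):
            assert (tmp_path / "a" / f"{name}.tsv").read_bytes() == (
                tmp_path / "b" / f"{name}.tsv"
            ).read_bytes()

    def test_different_seeds_give_different_genotypes(self, snps):
        a = generate_genotypes(one_phecode_config(5000, seed=1, snp_list=snps))
        b = generate_genotypes(one_phecode_config(5000, seed=2, snp_list=snps))
        assert not a.equals(b)
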