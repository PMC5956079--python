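"""Synthetic-cohort generator: calibration, closed-form checks, and
agreement between the individual-level and direct generation paths."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from adipoclass.errors import ParameterError
from adipoclass.synthetic import (
    ArchitectureSpec,
    cohort_to_sumstats,
    inverse_normal_transform,
    simulate_cohort,
    sumstats_direct,
)


class TestSpecValidation:
    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            ArchitectureSpec(n_concordant=-1)

    def test_maf_range_bounds(self):
        with pytest.raises(ParameterError):
            ArchitectureSpec(maf_range=(0.0, 0.5))
        with pytest.raises(ParameterError):
            ArchitectureSpec(maf_range=(0.1, 0.6))

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ParameterError):
            ArchitectureSpec(n_individuals=30)

    def test_infeasible_noise_decomposition_rejected(self):
        # huge genetic effects leave no residual variance for the target
        # phenotype correlation
        spec = ArchitectureSpec(
            n_concordant=400, n_bmi_only=0, n_whr_only=0, n_discordant=0,
            effect_size_bmi=0.08, effect_size_whr=0.0, r_target=0.44,
            n_individuals=1_000, seed=0,
        )
        with pytest.raises(ParameterError):
            simulate_cohort(spec)


class TestCohort:
    def test_null_genetics_recovers_target_correlation(self, null_spec):
        cohort = simulate_cohort(null_spec)
        r = np.corrcoef(cohort.phenotype_bmi, cohort.phenotype_whr)[0, 1]
        assert r == pytest.approx(0.5, abs=0.03)

    def test_genotype_frequencies_match_mafs(self, null_spec):
        cohort = simulate_cohort(null_spec)
        freqs = cohort.genotypes.mean(axis=0) / 2
        maf = cohort.truth["maf"].to_numpy()
        se = np.sqrt(maf * (1 - maf) / (2 * null_spec.n_individuals))
        assert np.all(np.abs(freqs - maf) < 5 * se)

    def test_truth_labels_partition_variants(self, default_spec):
        cohort = simulate_cohort(default_spec)
        counts = cohort.truth["true_class"].value_counts().to_dict()
        assert counts == default_spec.class_counts
        assert len(cohort.truth) == default_spec.n_variants

    def test_null_disease_association_is_calibrated(self, null_spec):
        cohort = simulate_cohort(null_spec)
        tables = cohort_to_sumstats(cohort, traits=("DISEASE",))
        z = tables[("DISEASE", "combined")]["beta"] / tables[("DISEASE", "combined")]["se"]
        # standard-normal z under no causal effect
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert z.abs().max() < 4.5

    def test_seeded_determinism_bit_identical(self, null_spec):
        a = simulate_cohort(null_spec)
        b = simulate_cohort(null_spec)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.phenotype_bmi, b.phenotype_bmi)
        np.testing.assert_array_equal(a.disease, b.disease)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestCohortSumstats:
    def test_mean_gws_z_matches_noncentrality(self):
        # per-variant z should average b*sqrt(2 f (1-f) N): 0.05 *
        # sqrt(2*0.3*0.7*50000) ~ 7.25
        spec = ArchitectureSpec(
            n_concordant=50, n_bmi_only=0, n_whr_only=0, n_discordant=0,
            effect_size_bmi=0.05, effect_size_whr=0.022,
            maf_range=(0.3, 0.3), n_individuals=50_000, seed=3,
        )
        cohort = simulate_cohort(spec)
        tab = cohort_to_sumstats(cohort, traits=("BMI",))[("BMI", "combined")]
        z = (tab["beta"] / tab["se"]).to_numpy()
        expected = 0.05 * np.sqrt(2 * 0.3 * 0.7 * 50_000)
        assert z.mean() == pytest.approx(expected, abs=3 / np.sqrt(50) + 0.1)

    def test_null_variant_z_within_bounds(self, null_spec):
        cohort = simulate_cohort(null_spec)
        tab = cohort_to_sumstats(cohort, traits=("BMI",))[("BMI", "combined")]
        # |z| < 3.9 holds for ~99.99% of null draws; 50 variants here
        assert (np.abs(tab["beta"] / tab["se"]) < 3.9).all()

    def test_identical_phenotypes_give_identical_sumstats(self, null_spec):
        cohort = simulate_cohort(null_spec)
        cohort.phenotype_whr = cohort.phenotype_bmi.copy()
        tables = cohort_to_sumstats(cohort, traits=("BMI", "WHR"))
        bmi = tables[("BMI", "combined")].drop(columns="trait")
        whr = tables[("WHR", "combined")].drop(columns="trait")
        pd.testing.assert_frame_equal(bmi, whr)

    def test_adjusted_effect_tracks_conversion_relation(self, default_spec):
        # b_WHRadjBMI ~ b_WHR - r*b_BMI within 2 SE per variant (r = the
        # realized phenotype correlation); the inverse-normal rescaling of
        # the residual adds a ~1/sqrt(1-r^2) factor well inside that band
        cohort = simulate_cohort(default_spec)
        r = np.corrcoef(cohort.phenotype_bmi, cohort.phenotype_whr)[0, 1]
        tabs = cohort_to_sumstats(cohort)
        bmi = tabs[("BMI", "combined")]
        whr = tabs[("WHR", "combined")]
        adj = tabs[("WHRadjBMI", "combined")]
        diff = adj["beta"] - (whr["beta"] - r * bmi["beta"])
        assert (diff.abs() < 2 * adj["se"]).all()

    def test_monomorphic_variant_emits_missing_beta(self, null_spec):
        cohort = simulate_cohort(null_spec)
        cohort.genotypes[:, 0] = 0
        tab = cohort_to_sumstats(cohort, traits=("BMI",))[("BMI", "combined")]
        assert np.isnan(tab["beta"].iloc[0])
        assert tab["beta"].iloc[1:].notna().all()

    def test_sex_strata_meta_consistent_with_combined(self, default_spec):
        from adipoclass.algebra import ivw_meta
        from adipoclass.pipeline import effect_from_row

        cohort = simulate_cohort(default_spec)
        tabs = cohort_to_sumstats(cohort, traits=("BMI",), strata=("combined", "women", "men"))
        comb = tabs[("BMI", "combined")]
        women = tabs[("BMI", "women")]
        men = tabs[("BMI", "men")]
        for i in range(0, len(comb), 7):
            meta = ivw_meta(
                [effect_from_row(women.iloc[i], "BMI"), effect_from_row(men.iloc[i], "BMI")]
            )
            assert abs(meta.beta - comb["beta"].iloc[i]) < 2 * comb["se"].iloc[i]


class TestDirect:
    def test_se_formula_substitution(self):
        spec = ArchitectureSpec(
            n_concordant=1, n_bmi_only=0, n_whr_only=0, n_discordant=0,
            maf_range=(0.5, 0.5), n_individuals=10_000, seed=0,
        )
        tab = sumstats_direct(spec)[("BMI", "combined")]
        assert tab["se"].iloc[0] == pytest.approx(1 / np.sqrt(5_000))

    def test_null_pvalue_calibration(self):
        spec = ArchitectureSpec(
            n_concordant=100_000, n_bmi_only=0, n_whr_only=0, n_discordant=0,
            effect_size_bmi=0.0, effect_size_whr=0.0,
            n_individuals=200_000, seed=9,
        )
        tab = sumstats_direct(spec)[("BMI", "combined")]
        frac = (tab["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.005)

    def test_error_correlation_matches_r_target(self):
        spec = ArchitectureSpec(
            n_concordant=100_000, n_bmi_only=0, n_whr_only=0, n_discordant=0,
            effect_size_bmi=0.0, effect_size_whr=0.0, r_target=0.44,
            n_individuals=200_000, seed=13,
        )
        tabs = sumstats_direct(spec)
        r = np.corrcoef(tabs[("BMI", "combined")]["beta"], tabs[("WHR", "combined")]["beta"])[0, 1]
        assert r == pytest.approx(0.44, abs=0.01)

    def test_parameter_recovery_over_replicates(self):
        spec = ArchitectureSpec(
            n_concordant=4, n_bmi_only=2, n_whr_only=2, n_discordant=2,
            maf_range=(0.3, 0.3), n_individuals=50_000,
        )
        reps = [
            sumstats_direct(replace(spec, seed=i))[("BMI", "combined")]["beta"].to_numpy()
            for i in range(200)
        ]
        mean_beta = np.mean(reps, axis=0)
        se = 1 / np.sqrt(2 * 0.3 * 0.7 * 50_000)
        mc_se = se / np.sqrt(200)
        from adipoclass.synthetic import build_truth

        true_beta = build_truth(spec, np.random.default_rng(spec.seed))["true_beta_bmi"]
        assert np.all(np.abs(mean_beta - true_beta) < 3 * mc_se)

    def test_seeded_determinism(self, default_spec):
        a = sumstats_direct(default_spec)
        b = sumstats_direct(default_spec)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])


class TestPathAgreement:
    def test_two_generation_paths_agree_in_distribution(self):
        # KS on z-scores over 10^4 null variants: the direct draw and the
        # cohort regression must produce the same sampling distribution
        spec = ArchitectureSpec(
            n_concordant=10_000, n_bmi_only=0, n_whr_only=0, n_discordant=0,
            effect_size_bmi=0.0, effect_size_whr=0.0, r_target=0.44,
            n_individuals=11_000, seed=21,
        )
        direct = sumstats_direct(spec)[("BMI", "combined")]
        cohort = simulate_cohort(spec)
        regressed = cohort_to_sumstats(cohort, traits=("BMI",))[("BMI", "combined")]
        z_direct = (direct["beta"] / direct["se"]).to_numpy()
        z_cohort = (regressed["beta"] / regressed["se"]).to_numpy()
        assert stats.ks_2samp(z_direct, z_cohort).pvalue > 0.001


class TestINT:
    def test_blom_transform_is_monotone_and_standardized(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=5_000)
        z = inverse_normal_transform(x)
        assert np.all(np.diff(z[np.argsort(x)]) >= 0)
        assert z.mean() == pytest.approx(0.0, abs=0.01)
        assert z.std() == pytest.approx(1.0, abs=0.01)
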