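import math

import numpy as np
import pandas as pd
import pytest

from snpindex.data_model import SNPSpec, PanelSpec
from snpindex.survival import cox_fit
from snpindex.synthetic import (GeneratorConfig, generate_cohort,
                                simulate_covariates, simulate_genotypes,
                                simulate_survival)
from snpindex.association import count_genotypes, allele_stats

C3 = SNPSpec("rs2287845", "C3", "T", "C")


class TestSimulateGenotypes:
    def test_maf_zero_all_wild(self):
        genos = simulate_genotypes(50, C3, 0.0, seed=1)
        assert all(g.to_string() == "TT" for g in genos)

    def test_maf_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, C3, 1.2, seed=1)

    def test_hwe_fractions_at_half(self):
        n = 100_000
        genos = simulate_genotypes(n, C3, 0.5, seed=2)
        nv = np.array([g.n_variant(C3) for g in genos])
        for level, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
            sd = math.sqrt(p * (1 - p) / n)
            assert abs((nv == level).mean() - p) < 3 * sd

    def test_variant_homozygote_fraction_low_maf(self):
        # q = 0.141 gives q^2 ~ 2.0% variant homozygotes
        n = 100_000
        genos = simulate_genotypes(n, C3, 0.141, seed=3)
        nv = np.array([g.n_variant(C3) for g in genos])
        p = 0.141 ** 2
        sd = math.sqrt(p * (1 - p) / n)
        assert abs((nv == 2).mean() - p) < 3 * sd

    def test_hwe_test_rejects_at_nominal_rate(self):
        rejections = 0
        reps = 200
        for r in range(reps):
            genos = simulate_genotypes(600, C3, 0.3, seed=1000 + r)
            counts = [0, 0, 0]
            for g in genos:
                counts[g.n_variant(C3)] += 1
            from snpindex.association import GenotypeCounts
            _, p = allele_stats(GenotypeCounts(*counts))
            rejections += p < 0.05
        rate = rejections / reps
        sd = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * sd


class TestSimulateCovariates:
    def test_prevalence_one_gives_constant(self):
        cfg = GeneratorConfig()
        cfg.covariate_prev = dict(cfg.covariate_prev, male=1.0)
        df = simulate_covariates(500, cfg, seed=1)
        assert (df["sex"] == "male").all()

    def test_large_sample_prevalences(self):
        n = 100_000
        df = simulate_covariates(n, GeneratorConfig(), seed=2)
        p = 489 / 814  # stage-I prevalence
        sd = math.sqrt(p * (1 - p) / n)
        assert abs((df["stage"] == "I").mean() - p) < 3 * sd

    def test_default_cohort_male_fraction(self):
        df = simulate_covariates(814, GeneratorConfig(), seed=3)
        assert (df["sex"] == "male").mean() == pytest.approx(0.735, abs=0.05)

    def test_bad_histology_probs_rejected(self):
        cfg = GeneratorConfig(histology_probs=(0.5, 0.4, 0.2))
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_covariates(10, cfg, seed=1)

    def test_pack_years_only_for_ever_smokers(self):
        df = simulate_covariates(2000, GeneratorConfig(), seed=4)
        assert df.loc[df.smoking == "never", "pack_years"].isna().all()
        assert df.loc[df.smoking == "ever", "pack_years"].notna().all()


def _null_config(**kw):
    """Single-SNP zero-effect configuration."""
    spec = SNPSpec("rs1", "G1", "A", "G", genetic_model="dominant",
                   risk_direction="variant_is_risk")
    base = dict(
        panel=PanelSpec((spec,)), variant_freq={"rs1": 0.3},
        snp_loghr_os={"rs1": 0.0}, snp_loghr_dfs={"rs1": 0.0},
        covariate_loghr_os={}, covariate_loghr_dfs={}, missing_rate=0.0)
    base.update(kw)
    return GeneratorConfig(**base)


class TestSimulateSurvival:
    def test_closed_form_event_fraction(self):
        # all effects zero, rate lam, fixed cutoff C: P(event) = 1 - e^(-lam C)
        lam, C, n = 0.02, 48.0, 40_000
        cfg = _null_config(n=n, baseline_os_rate=lam, baseline_rec_rate=0.0,
                           accrual_months=0.0, cutoff_months=C,
                           round_to_month=False)
        cohort, _ = generate_cohort(cfg, seed=5)
        _, e = cohort.endpoint("os")
        p = 1 - math.exp(-lam * C)
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(e.mean() - p) < 3 * sd

    def test_zero_rate_all_censored_at_cutoff(self):
        cfg = _null_config(n=200, baseline_os_rate=0.0, baseline_rec_rate=0.0,
                           accrual_months=0.0, cutoff_months=60.0,
                           round_to_month=False)
        cohort, _ = generate_cohort(cfg, seed=6)
        t, e = cohort.endpoint("os")
        assert e.sum() == 0 and (t == 60.0).all()

    def test_two_group_hazard_ratio_recovery(self):
        cfg = _null_config(n=4000, snp_loghr_os={"rs1": math.log(2.0)},
                           baseline_os_rate=0.004, baseline_rec_rate=0.0)
        cohort, _ = generate_cohort(cfg, seed=7)
        t, e = cohort.endpoint("os")
        spec = cfg.panel.snps[0]
        x = np.array([float(s.genotypes["rs1"].n_variant(spec) >= 1)
                      for s in cohort.subjects])
        fit = cox_fit(t, e, x[:, None], labels=["carrier"])
        assert abs(fit.coef[0] - math.log(2.0)) < 2 * fit.se[0]


class TestGenerateCohort:
    def test_fixed_seed_bit_identical(self):
        a, _ = generate_cohort(GeneratorConfig(n=120), seed=9)
        b, _ = generate_cohort(GeneratorConfig(n=120), seed=9)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(GeneratorConfig(n=120), seed=9)
        b, _ = generate_cohort(GeneratorConfig(n=120), seed=10)
        assert not a.to_frame().equals(b.to_frame())

    def test_subject_invariants_hold(self, default_cohort):
        cohort, _ = default_cohort
        assert cohort.n == 814
        for s in cohort.subjects:  # Cohort.__post_init__ validates; spot-check
            assert s.dfs_time <= s.os_time
            assert not (s.os_event == 1 and s.dfs_event == 0)

    def test_dfs_events_dominate_deaths(self, default_cohort):
        cohort, _ = default_cohort
        _, e_os = cohort.endpoint("os")
        _, e_dfs = cohort.endpoint("dfs")
        assert e_dfs.sum() >= e_os.sum()

    def test_adding_snp_does_not_perturb_covariates(self):
        full = GeneratorConfig(n=100)
        sub = GeneratorConfig(
            n=100, panel=PanelSpec(full.panel.snps[:4], full.panel.covariate_set))
        a, _ = generate_cohort(full, seed=11)
        b, _ = generate_cohort(sub, seed=11)
        cols = ["age_group", "sex", "smoking", "histology", "stage",
                "pack_years", "adjuvant_chemo"]
        pd.testing.assert_frame_equal(a.to_frame()[cols], b.to_frame()[cols])

    def test_missingness_injected_per_snp(self):
        cfg = GeneratorConfig(n=2000, missing_rate=0.05)
        cohort, _ = generate_cohort(cfg, seed=12)
        for sid in cohort.panel.snp_ids:
            counts = count_genotypes(cohort, sid)
            assert counts.total == 2000
            assert 0 < counts.n_missing < 300

    def test_true_effects_recorded(self, default_cohort):
        _, effects = default_cohort
        assert effects.snp_os["rs967591"] == pytest.approx(math.log(1.68))
        assert set(effects.snp_os) == set(effects.snp_dfs)
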