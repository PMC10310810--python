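"""Synthetic-cohort generator: marginals, determinism, confounding,
biomarkers, expression, and paired cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from genoscape.datatypes import CASE, FEMALE
from genoscape.qc import hwe_exact_test, genotype_counts
from genoscape.stats import eqtl_linear, wilcoxon_rank_sum
from genoscape.synth import (
    CohortConfig,
    make_cohort_pair,
    simulate_biomarkers,
    simulate_cohort,
    simulate_expression,
    simulate_genotypes,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_cases", 0),
            ("maf_range", (0.0, 0.4)),
            ("maf_range", (0.3, 0.6)),
            ("missing_rate", 1.0),
            ("population_prevalence", 0.0),
            ("age_sd", -1.0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = CohortConfig(**{field: value})
        with pytest.raises(ValueError, match=field):
            cfg.validate()

    def test_causal_slots_must_fit(self):
        cfg = CohortConfig(n_variants=10, causal_per_subtype=6)
        with pytest.raises(ValueError, match="causal_per_subtype"):
            cfg.validate()


class TestGenotypeMarginals:
    def test_mean_dosage_matches_hardy_weinberg(self):
        cfg = CohortConfig(
            n_cases=1000, n_controls=1000, n_variants=30, maf_range=(0.3, 0.3),
            ld_block_size=1, causal_per_subtype=2, missing_rate=0.0, seed=5,
        )
        geno = simulate_genotypes(cfg)
        # binomial(2, 0.3): mean 0.6, se = sqrt(2*0.3*0.7/n)
        se = np.sqrt(2 * 0.3 * 0.7 / 2000)
        assert np.abs(geno.dosages.mean(axis=0) - 0.6).max() < 4 * se

    def test_no_missing_when_rate_zero(self):
        cfg = CohortConfig(n_cases=50, n_controls=50, n_variants=100,
                           causal_per_subtype=3, missing_rate=0.0)
        geno = simulate_genotypes(cfg)
        assert not np.isnan(geno.dosages).any()

    def test_empirical_maf_tracks_generating_maf(self):
        cfg = CohortConfig(n_cases=1000, n_controls=1000, n_variants=200,
                           causal_per_subtype=5, missing_rate=0.0, seed=6)
        geno = simulate_genotypes(cfg)
        p_gen = geno.variant_meta["maf_gen"].to_numpy()
        p_emp = geno.allele_freq()
        se = np.sqrt(p_gen * (1 - p_gen) / (2 * 2000))
        assert (np.abs(p_emp - p_gen) < 4 * se).mean() > 0.97

    def test_hwe_p_values_approximately_uniform(self):
        cfg = CohortConfig(n_cases=500, n_controls=500, n_variants=1000,
                           ld_block_size=1, causal_per_subtype=10,
                           missing_rate=0.0, seed=8)
        geno = simulate_genotypes(cfg)
        pvals = np.array([
            hwe_exact_test(*genotype_counts(geno.dosages[:, j]))
            for j in range(geno.n_variants)
        ])
        # exact-test p-values are discrete and conservative; check the
        # bulk of the distribution is not depleted of large values
        assert kstest(pvals, "uniform").statistic < 0.15
        assert (pvals < 0.001).mean() < 0.01

    def test_determinism_bit_identical(self):
        cfg = CohortConfig(n_cases=60, n_controls=60, n_variants=150,
                           causal_per_subtype=3, seed=9)
        a, ta = simulate_cohort(cfg)
        b, tb = simulate_cohort(cfg)
        assert a.equals(b)
        assert (ta.subtype == tb.subtype).all()


@pytest.fixture(scope="module")
def cohort():
    cfg = CohortConfig(n_cases=800, n_controls=800, n_variants=800,
                       causal_per_subtype=8, seed=10)
    return simulate_cohort(cfg), cfg


class TestPhenotypes:

    def test_exact_quota(self, cohort):
        (geno, truth), cfg = cohort
        assert int(geno.is_case.sum()) == 800
        assert int(geno.is_control.sum()) == 800

    def test_cases_older_and_more_female(self, cohort):
        (geno, truth), cfg = cohort
        age = geno.subject_meta["age"]
        sex = geno.subject_meta["sex"]
        assert age[geno.is_case].mean() > age[geno.is_control].mean() + 1.0
        assert (sex[geno.is_case] == FEMALE).mean() > (
            (sex[geno.is_control] == FEMALE).mean()
        )

    def test_shared_risk_alleles_enriched_in_cases(self, cohort):
        (geno, truth), cfg = cohort
        j = geno.variant_meta.index.get_loc(truth.shared_risk_variant)
        d = geno.dosages[:, j]
        case_freq = np.nanmean(d[geno.is_case])
        control_freq = np.nanmean(d[geno.is_control])
        assert case_freq > control_freq

    def test_quota_unreachable_raises(self):
        # null effects and equal covariate distributions pin the case rate
        # at the population prevalence, far below the requested quota
        cfg = CohortConfig(n_cases=500, n_controls=10, n_variants=150,
                           causal_per_subtype=3, effect_size_range=(0.0, 0.0),
                           apoe_like_effect=0.0, age_mean_case=75.0,
                           age_mean_control=75.0, female_odds_case=1.0,
                           female_odds_control=1.0,
                           population_prevalence=0.001, seed=11)
        with pytest.raises(RuntimeError, match="quota"):
            simulate_cohort(cfg)


class TestBiomarkers:
    def _labels(self, n_per_arm, rng):
        ids = [f"s{i}" for i in range(2 * n_per_arm)]
        subject_meta = pd.DataFrame(
            {"phenotype": [CASE] * n_per_arm + [1] * n_per_arm,
             "age": 75.0, "sex": 1.0}, index=ids,
        )
        from genoscape.datatypes import TruthLabels

        subtype = pd.Series([2] * n_per_arm + [2] * n_per_arm, index=ids)
        truth = TruthLabels(subtype=subtype, causal_variants={},
                            shared_risk_variants=["x"], shared_risk_effect=0.0)
        return truth, subject_meta

    def test_all_values_positive(self):
        rng = np.random.default_rng(12)
        truth, meta = self._labels(100, rng)
        cfg = CohortConfig(seed=12)
        table = simulate_biomarkers(truth, meta, cfg)
        assert (table.to_numpy() > 0).all()

    def test_albumin_shift_detectable_in_most_seeds(self):
        hits = 0
        reps = 60
        for rep in range(reps):
            cfg = CohortConfig(seed=1000 + rep, albumin_shift_sd=0.5)
            truth, meta = self._labels(350, np.random.default_rng(rep))
            table = simulate_biomarkers(truth, meta, cfg)
            is_case = meta["phenotype"] == CASE
            p = wilcoxon_rank_sum(table.loc[is_case, "albumin"],
                                  table.loc[~is_case, "albumin"])
            hits += p < 0.05
        assert hits / reps > 0.8

    def test_null_markers_have_uniform_p(self):
        ps = []
        for rep in range(60):
            cfg = CohortConfig(seed=2000 + rep)
            truth, meta = self._labels(100, np.random.default_rng(rep))
            table = simulate_biomarkers(truth, meta, cfg)
            is_case = meta["phenotype"] == CASE
            ps.append(wilcoxon_rank_sum(table.loc[is_case, "hba1c"],
                                        table.loc[~is_case, "hba1c"]))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestExpression:
    def test_beta_recovered_within_two_se(self, tiny_cohort):
        geno, truth = tiny_cohort
        vid = truth.shared_risk_variant
        expr = simulate_expression(geno, vid, beta=1.0, noise_sd=0.1, seed=13)
        j = geno.variant_meta.index.get_loc(vid)
        d = geno.dosages[:, j]
        ok = ~np.isnan(d)
        beta, se, p = eqtl_linear(
            expr.to_numpy()[ok], d[ok],
            geno.subject_meta["age"].to_numpy()[ok],
            geno.subject_meta["sex"].to_numpy()[ok],
        )
        assert abs(beta - 1.0) < 2 * se

    def test_unknown_variant_rejected(self, tiny_cohort):
        geno, _ = tiny_cohort
        with pytest.raises(KeyError, match="nope"):
            simulate_expression(geno, "nope", seed=1)

    def test_deterministic(self, tiny_cohort):
        geno, truth = tiny_cohort
        a = simulate_expression(geno, truth.shared_risk_variant, seed=14)
        b = simulate_expression(geno, truth.shared_risk_variant, seed=14)
        assert (a == b).all()


class TestCohortPair:
    def _configs(self, n_variants=400):
        d = CohortConfig(n_cases=80, n_controls=80, n_variants=n_variants,
                         causal_per_subtype=4, seed=15)
        v = CohortConfig(n_cases=60, n_controls=90, n_variants=n_variants,
                         causal_per_subtype=4, seed=16)
        return d, v

    def test_overlap_one_shares_all_identifiers(self):
        d, v = self._configs()
        pair = make_cohort_pair(d, v, 1.0)
        assert set(pair.discovery.variant_ids) == set(pair.validation.variant_ids)

    def test_overlap_fraction_exact(self):
        d, v = self._configs(n_variants=1000)
        pair = make_cohort_pair(d, v, 0.8)
        shared = set(pair.discovery.variant_ids) & set(pair.validation.variant_ids)
        assert len(shared) == 800
        assert set(pair.shared_variants) == shared

    def test_subjects_disjoint_and_causal_sets_identical(self):
        d, v = self._configs()
        pair = make_cohort_pair(d, v, 0.8)
        assert not (set(pair.discovery.subject_ids)
                    & set(pair.validation.subject_ids))
        assert pair.discovery_truth.causal_variants == \
            pair.validation_truth.causal_variants

    def test_overlap_out_of_range_rejected(self):
        d, v = self._configs()
        with pytest.raises(ValueError, match="overlap"):
            make_cohort_pair(d, v, 0.0)
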