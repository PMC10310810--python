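"""Marker/sample QC and LD pruning against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

from genoscape.qc import (
    QcThresholds,
    filter_samples,
    filter_variants,
    hwe_exact_test,
    ld_prune,
    pi_hat_matrix,
)
from tests.conftest import make_dataset


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional heterozygote
    distribution, independent of the log-gamma implementation."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    probs = {}
    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        a = (rare - h) // 2
        b = (2 * n - rare - h) // 2
        probs[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(a) * math.factorial(h) * math.factorial(b),
        )
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((100, 0, 0), 1.0),     # monomorphic: single attainable table
            ((25, 50, 25), 1.0),    # observed count is modal
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected)

    def test_extreme_heterozygosity(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 101))
            counts = rng.multinomial(n, [0.4, 0.4, 0.2])
            assert hwe_exact_test(*counts) == pytest.approx(
                hwe_oracle(*counts), rel=1e-9
            )

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestVariantFilters:
    def test_call_rate_removal(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        d[:6, 0] = np.nan  # call rate 0.94 < 0.95
        geno = make_dataset(d)
        kept, report = filter_variants(geno, QcThresholds(hwe_p_min=0.0))
        assert report.removed_by("variant_call_rate") == ["v0"]
        assert list(kept.variant_ids) == ["v1", "v2"]

    def test_maf_removal(self):
        d = np.zeros((2000, 2))
        d[0, 0] = 1.0  # MAF 0.00025 < 0.001
        d[:, 1] = np.tile([0, 1, 2, 1], 500)
        geno = make_dataset(d)
        kept, report = filter_variants(geno, QcThresholds(hwe_p_min=0.0))
        assert report.removed_by("variant_maf") == ["v0"]

    def test_all_passing_reports_zero_removals(self):
        rng = np.random.default_rng(2)
        geno = make_dataset(rng.binomial(2, 0.4, size=(500, 5)).astype(float))
        kept, report = filter_variants(geno)
        assert kept.n_variants == 5
        assert all(s["n_removed"] == 0 for s in report.stages)

    def test_survivor_counts_non_increasing(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, size=(300, 50)).astype(float)
        d[np.unravel_index(rng.choice(d.size, 500, replace=False), d.shape)] = np.nan
        geno = make_dataset(d)
        _, report = filter_variants(geno, QcThresholds(geno_call_rate=0.97))
        counts = [s["n_variants_remaining"] for s in report.stages]
        assert counts == sorted(counts, reverse=True)


class TestSampleFilters:
    def test_high_missingness_removed(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, size=(20, 100)).astype(float)
        d[0, :10] = np.nan  # 10% missing > 5%
        geno = make_dataset(d)
        kept, report = filter_samples(geno)
        assert "s0" in report.removed_by("sample_missingness")

    def test_duplicate_subject_flagged_by_pihat(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.4, size=(30, 800)).astype(float)
        d[1] = d[0]  # duplicated subject: PI_HAT ~ 1
        geno = make_dataset(d)
        pihat = pi_hat_matrix(geno)
        assert pihat[0, 1] > 0.9
        kept, report = filter_samples(geno)
        assert len(report.removed_by("sample_relatedness")) == 1

    def test_unrelated_subjects_not_removed(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 1000), size=(40, 1000)).astype(float)
        geno = make_dataset(d)
        pihat = pi_hat_matrix(geno)
        iu = np.triu_indices(40, 1)
        assert np.median(pihat[iu]) < 0.05
        _, report = filter_samples(geno)
        assert report.removed_by("sample_relatedness") == []


def greedy_prune_oracle(D, maf, pos, window, step, r2max):
    """Independent re-simulation of the windowed greedy rule."""
    m = D.shape[1]
    keep = [True] * m
    start = 0
    while True:
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        while len(idx) > 1:
            best, pair = 0.0, None
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    r = np.corrcoef(D[:, idx[a]], D[:, idx[b]])[0, 1] ** 2
                    if r > best:
                        best, pair = r, (idx[a], idx[b])
            if best <= r2max:
                break
            va, vb = pair
            victim = va if (maf[va], -pos[va]) < (maf[vb], -pos[vb]) else vb
            keep[victim] = False
            idx.remove(victim)
        if start + window >= m:
            break
        start += step
    return [j for j in range(m) if keep[j]]


class TestLdPrune:
    def test_identical_columns_keep_one(self):
        rng = np.random.default_rng(7)
        col = rng.binomial(2, 0.4, 200).astype(float)
        d = np.column_stack([col, col, rng.binomial(2, 0.4, 200)])
        geno = make_dataset(d)
        kept = ld_prune(geno)
        assert sum(v in kept for v in ("v0", "v1")) == 1

    def test_independent_variants_all_kept(self):
        rng = np.random.default_rng(8)
        geno = make_dataset(rng.binomial(2, 0.4, size=(500, 20)).astype(float))
        assert len(ld_prune(geno)) == 20

    def test_matches_greedy_oracle_on_correlation_chain(self):
        rng = np.random.default_rng(9)
        n = 400
        base = rng.binomial(2, 0.4, n).astype(float)
        cols = [base]
        for _ in range(4):
            prev = cols[-1]
            fresh = rng.binomial(2, 0.4, n).astype(float)
            mask = rng.random(n) < 0.3
            cols.append(np.where(mask, fresh, prev))
        D = np.column_stack(cols)
        geno = make_dataset(D)
        thr = QcThresholds(prune_window=5, prune_step=2, prune_r2=0.1)
        kept = ld_prune(geno, thr)
        maf = geno.minor_allele_freq()
        pos = geno.variant_meta["pos"].to_numpy()
        expected = greedy_prune_oracle(D, maf, pos, 5, 2, 0.1)
        assert kept == [f"v{j}" for j in expected]

    def test_idempotent_and_no_violating_pairs(self):
        rng = np.random.default_rng(10)
        base = rng.binomial(2, 0.3, size=(300, 30)).astype(float)
        for j in range(1, 30, 3):
            mask = rng.random(300) < 0.5
            base[:, j] = np.where(mask, base[:, j - 1], base[:, j])
        geno = make_dataset(base)
        kept = ld_prune(geno)
        pruned = geno.subset(variants=np.asarray(kept))
        assert ld_prune(pruned) == kept
        D = pruned.dosages
        thr = QcThresholds()
        for a in range(D.shape[1]):
            for b in range(a + 1, min(a + thr.prune_window, D.shape[1])):
                assert np.corrcoef(D[:, a], D[:, b])[0, 1] ** 2 <= thr.prune_r2 + 1e-12


def test_threshold_validation():
    with pytest.raises(ValueError):
        QcThresholds(prune_step=100, prune_window=50).validate()
    with pytest.raises(ValueError):
        QcThresholds(maf_min=0.9).validate()
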