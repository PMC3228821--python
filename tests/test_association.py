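import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from icaqtl import (
    anova_2df,
    hwe_exact_test,
    mediation_adjust,
    module_enrichment_step,
    pattern_phenotype_corr,
    scan,
    snp_qc,
    study_wise_threshold,
)
from icaqtl.containers import GeneModule, GenotypeMatrix
from icaqtl.simulate import simulate_genotypes


def make_geno(counts):
    counts = np.asarray(counts, dtype=float)
    return GenotypeMatrix(
        counts=counts,
        snp_ids=[f"rs{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
    )


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by integer combinatorics over all genotype configurations
    with the observed allele counts (independent of the implementation)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab  # count of the 'a' allele
    probs = {}
    for ab in range(na % 2, min(na, 2 * n - na) + 1, 2):
        aa = (na - ab) // 2
        bb = n - aa - ab
        if bb < 0:
            continue
        w = Fraction(math.factorial(n), math.factorial(aa) * math.factorial(ab) * math.factorial(bb))
        probs[ab] = w * Fraction(2) ** ab
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return float(sum(v for v in probs.values() if v <= p_obs) / total)


class TestHWE:
    def test_all_heterozygotes_rejected(self):
        assert hwe_exact_test(0, 50, 0) < 1e-10

    def test_hw_proportions_retained(self):
        assert hwe_exact_test(25, 50, 25) >= 1e-4

    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 13):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                        hwe_oracle(n_aa, n_ab, n_bb), abs=1e-10
                    )


class TestSnpQC:
    def test_filters_on_maf_hwe_call_rate(self):
        n = 100
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.3, n).astype(float)
        mono = np.zeros(n)
        all_het = np.ones(n)
        low_call = good.copy()
        low_call[:20] = np.nan
        g = make_geno(np.vstack([good, mono, all_het, low_call]))
        kept, report = snp_qc(g)
        assert kept.snp_ids == ["rs0"]
        assert list(report["kept"]) == [True, False, False, False]


class TestAnova:
    def test_equal_class_means_null(self):
        y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        geno = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        rec = anova_2df(y, geno)
        assert rec.F == pytest.approx(0.0) and rec.p == pytest.approx(1.0)

    def test_matches_hand_computed_sums_of_squares(self):
        # 3 classes of 4 samples with distinct means plus fixed perturbations
        y = np.array(
            [5.1, 4.9, 5.2, 4.8, 7.3, 6.9, 7.1, 6.7, 9.4, 9.0, 9.3, 8.9]
        )
        geno = np.repeat([0.0, 1.0, 2.0], 4)
        rec = anova_2df(y, geno)
        grand = y.mean()
        ssb = sum(4 * (y[g * 4 : g * 4 + 4].mean() - grand) ** 2 for g in range(3))
        ssw = sum(
            ((y[g * 4 : g * 4 + 4] - y[g * 4 : g * 4 + 4].mean()) ** 2).sum()
            for g in range(3)
        )
        assert rec.F == pytest.approx((ssb / 2) / (ssw / 9), abs=1e-10)
        assert rec.r2 == pytest.approx(ssb / (ssb + ssw), abs=1e-12)
        # independent route: scipy's one-way ANOVA
        F_sp, p_sp = stats.f_oneway(y[:4], y[4:8], y[8:])
        assert rec.F == pytest.approx(F_sp, rel=1e-12)
        assert rec.p == pytest.approx(p_sp, rel=1e-12)

    def test_two_classes_one_df(self):
        rng = np.random.default_rng(1)
        rec = anova_2df(rng.standard_normal(30), np.repeat([0.0, 1.0], 15))
        assert rec.df_between == 1

    def test_single_class_untestable(self):
        rec = anova_2df(np.arange(5.0), np.zeros(5))
        assert not rec.testable and rec.p == 1.0 and rec.r2 == 0.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        n = 60
        geno = rng.binomial(2, 0.3, n).astype(float)
        Y = rng.standard_normal((10_000, n))
        from icaqtl.association import _scan_one_snp

        _, p, *_ = _scan_one_snp(Y, geno)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestScan:
    def test_null_panel_yields_no_hits(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            g = simulate_genotypes(1000, 200, [0.3], seed=seed)
            pats = rng.standard_normal((10, 200))
            recs, n_tests = scan(pats, [f"P{i}" for i in range(10)], g,
                                 g.sample_ids, p_max=1e-7)
            assert recs == [] and n_tests == 10_000

    def test_planted_effect_detected(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            g = simulate_genotypes(20, 300, [0.3], seed=seed)
            dose = g.counts[4]
            beta = np.sqrt(0.2 / (1 - 0.2) / (2 * 0.3 * 0.7))
            pat = beta * (dose - dose.mean()) + rng.standard_normal(300)
            recs, _ = scan(pat[None, :], ["P0"], g, g.sample_ids, p_max=1e-7)
            assert any(r.snp_id == g.snp_ids[4] for r in recs)

    def test_p_max_one_returns_everything(self):
        rng = np.random.default_rng(3)
        g = simulate_genotypes(7, 50, [0.4], seed=3)
        recs, n_tests = scan(rng.standard_normal((3, 50)),
                             ["a", "b", "c"], g, g.sample_ids, p_max=1.0 + 1e-12)
        assert len(recs) == n_tests == 21

    def test_sample_mismatch_fails(self):
        g = simulate_genotypes(2, 10, [0.4], seed=4)
        with pytest.raises(ValueError, match="sample ids differ"):
            scan(np.zeros((1, 10)), ["a"], g, [f"x{i}" for i in range(10)], 1.0)


class TestStudyWiseThreshold:
    def test_printed_value_reproduced(self):
        assert study_wise_threshold(64, 675_350, 0.05) == pytest.approx(
            1.15e-9, rel=1e-12
        )

    @pytest.mark.parametrize(
        "m,s,expect", [(1, 1, 0.05), (10, 10, 5e-4)]
    )
    def test_simple_arithmetic(self, m, s, expect):
        assert study_wise_threshold(m, s, 0.05) == pytest.approx(expect, rel=1e-12)

    def test_zero_counts_fail(self):
        with pytest.raises(ValueError):
            study_wise_threshold(0, 10)


class TestModuleEnrichmentStep:
    def module(self, genes):
        return GeneModule("M", list(genes), np.ones(len(genes)), np.zeros(len(genes)))

    def test_no_hit_overlap_fails(self):
        universe = [f"g{i}" for i in range(100)]
        er = module_enrichment_step(
            self.module(universe[:10]), set(universe[50:60]), universe, threshold=0.05
        )
        assert er.p == 1.0 and not er.passed

    def test_exact_tail_by_direct_summation(self):
        N, K, n, k = 1000, 20, 50, 15
        expect = sum(
            math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
        ) / math.comb(N, n)
        universe = [f"g{i}" for i in range(N)]
        hits = set(universe[:K])
        module_genes = universe[:k] + universe[K : K + (n - k)]
        er = module_enrichment_step(self.module(module_genes), hits, universe, 1e-9)
        assert er.p == pytest.approx(expect, rel=1e-10)
        assert er.k_hit == k

    def test_saturated_boundary(self):
        universe = [f"g{i}" for i in range(10)]
        er = module_enrichment_step(self.module(universe), set(universe), universe, 0.05)
        assert er.p == 1.0


class TestMediation:
    def test_full_mediation_collapses_r2(self):
        rng = np.random.default_rng(5)
        n = 1000
        dose = rng.binomial(2, 0.3, n).astype(float)
        cis = 1.5 * dose + rng.standard_normal(n)
        trans = cis + rng.standard_normal(n)
        r2_un, r2_adj = mediation_adjust(trans, dose, [cis])
        assert r2_adj < 0.2 * r2_un

    def test_independent_mediators_leave_r2(self):
        rng = np.random.default_rng(6)
        n = 2000
        dose = rng.binomial(2, 0.3, n).astype(float)
        trans = 0.8 * dose + rng.standard_normal(n)
        med = [rng.standard_normal(n), rng.standard_normal(n)]
        r2_un, r2_adj = mediation_adjust(trans, dose, med)
        assert r2_adj == pytest.approx(r2_un, abs=0.02)

    def test_empty_mediator_list_identity(self):
        rng = np.random.default_rng(7)
        dose = rng.binomial(2, 0.4, 100).astype(float)
        y = rng.standard_normal(100)
        r2_un, r2_adj = mediation_adjust(y, dose, [])
        assert r2_un == r2_adj


class TestPatternPhenotype:
    def test_identity_correlation(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(50)
        r, p = pattern_phenotype_corr(a, a)
        assert r == pytest.approx(1.0)

    def test_independent_near_zero(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            r, _ = pattern_phenotype_corr(
                rng.standard_normal(10_000), rng.standard_normal(10_000)
            )
            assert abs(r) < 0.05

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        n = 30
        a = rng.standard_normal(n)
        b = 0.5 * a + rng.standard_normal(n)
        r_obs, p_t = pattern_phenotype_corr(a, b)
        B = 100_000
        az = (a - a.mean()) / a.std()
        bz = (b - b.mean()) / b.std()
        perm_idx = np.argsort(rng.random((B, n)), axis=1)
        r_null = (az[perm_idx] @ bz) / n
        p_perm = (1 + (np.abs(r_null) >= abs(r_obs)).sum()) / (B + 1)
        mc_err = 3 * math.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(p_t - p_perm) < max(mc_err, 5e-4)

    def test_missing_dropped_pairwise(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        b = np.array([1.1, 2.2, 2.9, 4.2, 100.0])
        r, _ = pattern_phenotype_corr(a, b)
        assert r > 0.99

    def test_zero_variance_fails(self):
        with pytest.raises(ValueError, match="variance"):
            pattern_phenotype_corr(np.ones(10), np.arange(10.0))
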